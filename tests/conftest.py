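import itertools

import pytest

import omgnet as og


@pytest.fixture(scope="session")
def structure():
    return og.default_structure()


@pytest.fixture(scope="session")
def fixture_counts(structure):
    return og.load_training_counts(structure)


@pytest.fixture(scope="session")
def model(structure, fixture_counts):
    """The network fitted to the packaged training counts, prior 1.0."""
    return og.fit(fixture_counts.tables, structure, prior_strength=1.0)


@pytest.fixture(scope="session")
def records(structure, fixture_counts):
    """One admissible record-level expansion of the training counts."""
    return og.expand_fixture(fixture_counts, structure, seed=0)


def full_joint_table(structure, params):
    """Brute-force oracle: tabulate the entire joint, cell by cell.

    Independent of the package's inference path: walks every full
    assignment and multiplies CPT entries directly.
    """
    names = structure.names
    states = [structure[n].states for n in names]
    table = {}
    for combo in itertools.product(*states):
        a = dict(zip(names, combo))
        p = 1.0
        for n in names:
            r = structure.row_index(n, a)
            s = structure.state_index(n, a[n])
            p *= float(params[n][r, s])
        table[combo] = p
    return table


def oracle_conditional(structure, table, evidence, query):
    """Conditional from the tabulated joint by filtering and renormalising."""
    names = structure.names
    qi = names.index(query)
    ev_idx = {names.index(k): v for k, v in evidence.items()}
    totals = {s: 0.0 for s in structure[query].states}
    for combo, p in table.items():
        if all(combo[i] == v for i, v in ev_idx.items()):
            totals[combo[qi]] += p
    z = sum(totals.values())
    return [totals[s] / z for s in structure[query].states]
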