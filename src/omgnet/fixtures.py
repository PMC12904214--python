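"""The packaged training cohort: published counts and a record-level expansion.

The training data are shipped as per-CPT counts (the sufficient statistics
of the model) together with per-stratum missingness tallies.  The true
record-level joint of the 89 patients across different tests is not
recoverable from those margins, so :func:`expand_fixture` emits *one
admissible* record set: within each disease stratum it assigns each test's
observed values and missing slots to patients by a seeded shuffle,
independently across tests.  Every per-CPT count (and hence every fitted
posterior, and every single-predictor evaluation) of the expansion matches
the fixture exactly; cross-test joint behaviour is synthetic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .dataio import PatientRecord
from .errors import ConfigurationError
from .model import CountTable, count_records
from .network import NetworkStructure, default_structure

__all__ = ["FixtureCounts", "load_training_counts", "expand_fixture",
           "training_records"]


@dataclass
class FixtureCounts:
    """Per-CPT count tables plus provenance flags and per-stratum NA tallies."""

    tables: dict[str, CountTable]
    provenance: dict[tuple[str, tuple[str, ...]], str]  # (variable, parent config) -> printed|derived
    missing: dict[str, dict[str, int]] = field(default_factory=dict)  # variable -> outcome state -> NA count


def load_training_counts(structure: NetworkStructure | None = None) -> FixtureCounts:
    """Load the packaged training-cohort counts, validated against the structure."""
    if structure is None:
        structure = default_structure()
    raw = yaml.safe_load(
        resources.files("omgnet.data").joinpath("training_counts.yaml").read_text()
    )["variables"]
    tables: dict[str, CountTable] = {}
    provenance: dict[tuple[str, tuple[str, ...]], str] = {}
    missing: dict[str, dict[str, int]] = {}
    for name in structure.names:
        if name not in raw:
            raise ConfigurationError(f"fixture lacks counts for variable {name!r}")
        spec = structure[name]
        configs = structure.parent_configs(name)
        counts = np.zeros((len(configs), len(spec.states)), dtype=np.int64)
        seen = set()
        for row in raw[name]["rows"]:
            parents = {str(k): str(v) for k, v in (row.get("parents") or {}).items()}
            r = structure.row_index(name, parents)
            seen.add(r)
            for state, c in row["counts"].items():
                counts[r, structure.state_index(name, str(state))] = int(c)
            provenance[(name, configs[r])] = str(row.get("provenance", "printed"))
        if seen != set(range(len(configs))):
            raise ConfigurationError(f"fixture rows for {name!r} do not cover all parent configs")
        tables[name] = CountTable(variable=name, states=spec.states,
                                  parent_configs=configs, counts=counts)
        if "missing" in raw[name]:
            missing[name] = {str(k): int(v) for k, v in raw[name]["missing"].items()}
    return FixtureCounts(tables=tables, provenance=provenance, missing=missing)


def _spread(values: list[str | None], rng: np.random.Generator) -> list[str | None]:
    rng.shuffle(values)
    return values


def expand_fixture(fixture: FixtureCounts | None = None,
                   structure: NetworkStructure | None = None,
                   seed: int = 0) -> list[PatientRecord]:
    """One admissible record-level expansion of the fixture counts.

    Within each outcome stratum, values of each variable (including missing
    slots) are dealt to patients by an independent seeded shuffle, except
    that the serology variable is dealt within (outcome, age) cells to honour
    its two-parent table.  ``count_records`` of the result reproduces every
    fixture table exactly; any mismatch raises :class:`ConfigurationError`
    naming the variable.
    """
    if structure is None:
        structure = default_structure()
    if fixture is None:
        fixture = load_training_counts(structure)
    rng = np.random.default_rng(seed)
    outcome = structure.outcome
    out_spec = structure[outcome]

    # Stratum sizes and per-stratum root assignments come from the outcome's
    # own table (rows indexed by its parents, e.g. sex).
    omg_table = fixture.tables[outcome]
    strata: dict[str, list[dict[str, str | None]]] = {s: [] for s in out_spec.states}
    for r, config in enumerate(omg_table.parent_configs):
        parents = dict(zip(out_spec.parents, config))
        for s_idx, state in enumerate(out_spec.states):
            for _ in range(int(omg_table.counts[r, s_idx])):
                strata[state].append({outcome: state, **parents})

    # The (outcome, age) joint is the row-sum margin of the serology table,
    # which is observed in every case.
    achr = fixture.tables["achr"]
    for state, patients in strata.items():
        ages: list[str | None] = []
        for r, config in enumerate(achr.parent_configs):
            cfg = dict(zip(structure["achr"].parents, config))
            if cfg[outcome] != state:
                continue
            ages.extend([cfg["age"]] * int(achr.counts[r].sum()))
        if len(ages) != len(patients):
            raise ConfigurationError(
                "fixture infeasible: serology row totals do not match the "
                f"{state!r} stratum size ({len(ages)} vs {len(patients)})"
            )
        for patient, age in zip(patients, _spread(ages, rng)):
            patient["age"] = age

    # Serology within (outcome, age) cells; every other child within its
    # outcome stratum, topping up with missing slots.
    for state, patients in strata.items():
        by_age: dict[str, list[dict]] = {}
        for p in patients:
            by_age.setdefault(p["age"], []).append(p)
        for r, config in enumerate(achr.parent_configs):
            cfg = dict(zip(structure["achr"].parents, config))
            if cfg[outcome] != state:
                continue
            cell = by_age.get(cfg["age"], [])
            values: list[str | None] = [
                s for s, c in zip(achr.states, achr.counts[r]) for _ in range(int(c))
            ]
            if len(values) != len(cell):
                raise ConfigurationError(
                    f"fixture infeasible for variable 'achr' in cell {cfg}"
                )
            for patient, v in zip(cell, _spread(values, rng)):
                patient["achr"] = v

    remaining = [n for n in structure.names
                 if n not in {outcome, "achr", "age", *out_spec.parents}]
    for name in remaining:
        table = fixture.tables[name]
        if structure[name].parents != (outcome,):
            raise ConfigurationError(
                f"expansion supports only {outcome!r}-parent tests, got {name!r}"
            )
        na = fixture.missing.get(name, {})
        for state, patients in strata.items():
            r = structure.row_index(name, {outcome: state})
            values = [
                s for s, c in zip(table.states, table.counts[r]) for _ in range(int(c))
            ] + [None] * int(na.get(state, 0))
            if len(values) != len(patients):
                raise ConfigurationError(
                    f"fixture infeasible for variable {name!r}: "
                    f"{len(values)} values for {len(patients)} patients in "
                    f"the {state!r} stratum"
                )
            for patient, v in zip(patients, _spread(values, rng)):
                patient[name] = v

    records = [PatientRecord(p) for ps in strata.values() for p in ps]
    rng.shuffle(records)

    recounted = count_records(records, structure)
    for name, table in fixture.tables.items():
        if not np.array_equal(recounted[name].counts, table.counts):
            raise ConfigurationError(
                f"expansion failed to reproduce fixture counts for {name!r}"
            )
    return records


def training_records(seed: int = 0) -> list[PatientRecord]:
    """Convenience: default structure, packaged counts, one expansion."""
    return expand_fixture(seed=seed)
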