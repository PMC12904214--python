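"""Sufficient statistics and Dirichlet-posterior conditional probability tables.

Each variable ``X`` with parents ``pa(X)`` owns one conditional probability
table (CPT).  Given state counts ``n_{x|u}`` per parent configuration ``u``
and a symmetric Dirichlet prior with concentration ``a`` per state, the
posterior of each CPT row is Dirichlet with concentrations
``alpha_{x|u} = a + n_{x|u}`` — the standard conjugate update.  The marginal
posterior of one entry ``p(X = x | u)`` is Beta(``alpha_{x|u}``,
``alpha_{.|u} - alpha_{x|u}``), and the credible summaries reported here are
its exact equal-tailed quantiles.

Complete-case handling is per table, not per record: a record contributes to
the CPT of ``X`` if and only if ``X`` and all parents of ``X`` are observed
in that record.  This makes every available observation count, matching the
available-case totals of the training cohort.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.stats import beta as beta_dist

from .dataio import PatientRecord
from .errors import ConfigurationError, SchemaError
from .network import NetworkStructure

__all__ = [
    "CountTable",
    "CredibleSummary",
    "FittedModel",
    "count_records",
    "fit",
]


@dataclass
class CountTable:
    """Observed state counts for one variable, one row per parent configuration."""

    variable: str
    states: tuple[str, ...]
    parent_configs: tuple[tuple[str, ...], ...]
    counts: np.ndarray  # (n_rows, n_states), non-negative integers

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.parent_configs), len(self.states)):
            raise ConfigurationError(
                f"count table for {self.variable!r} has shape {self.counts.shape}, "
                f"expected {(len(self.parent_configs), len(self.states))}"
            )
        if (self.counts < 0).any():
            raise ConfigurationError(f"negative count in table for {self.variable!r}")

    @property
    def n_used(self) -> int:
        """Number of cases contributing to this table (sum of all counts)."""
        return int(self.counts.sum())


def count_records(records: Iterable[PatientRecord],
                  structure: NetworkStructure) -> dict[str, CountTable]:
    """Tally per-CPT sufficient statistics from records.

    A record contributes to the table of ``X`` iff ``X`` and all parents of
    ``X`` are observed; partially observed records still inform every table
    they are complete for.  Undeclared variables or states raise
    :class:`SchemaError` naming the offending record.
    """
    tables = {
        name: CountTable(
            variable=name,
            states=structure[name].states,
            parent_configs=structure.parent_configs(name),
            counts=np.zeros((structure.n_rows(name), len(structure[name].states)), dtype=np.int64),
        )
        for name in structure.names
    }
    for i, record in enumerate(records):
        for name, value in record.items():
            if name not in structure:
                raise SchemaError(f"record {i}: unknown variable {name!r}")
            try:
                structure.state_index(name, value)
            except SchemaError as exc:
                raise SchemaError(f"record {i}: {exc}") from None
        for name in structure.names:
            spec = structure[name]
            if not record.observed(name, *spec.parents):
                continue
            try:
                r = structure.row_index(name, record)
                s = structure.state_index(name, record[name])
            except SchemaError as exc:
                raise SchemaError(f"record {i}: {exc}") from None
            tables[name].counts[r, s] += 1
    return tables


@dataclass(frozen=True)
class CredibleSummary:
    """Equal-tailed 95% posterior summary of one probability."""

    q025: float
    median: float
    q975: float

    def __post_init__(self) -> None:
        if not 0 <= self.q025 <= self.median <= self.q975 <= 1:
            raise ValueError(f"unordered credible summary {self}")

    def as_percent(self) -> tuple[float, float, float]:
        return (100 * self.q025, 100 * self.median, 100 * self.q975)


class FittedModel:
    """A network structure plus one Dirichlet posterior per CPT row.

    ``concentrations[name]`` has shape ``(n_rows, n_states)`` and equals
    ``prior_strength + counts`` entrywise.
    """

    def __init__(self, structure: NetworkStructure,
                 concentrations: Mapping[str, np.ndarray],
                 prior_strength: float = 1.0):
        if prior_strength <= 0:
            raise ConfigurationError("prior_strength must be positive")
        missing = set(structure.names) - set(concentrations)
        if missing:
            raise ConfigurationError(f"no posterior for variable(s) {sorted(missing)}")
        self.structure = structure
        self.prior_strength = float(prior_strength)
        self.concentrations: dict[str, np.ndarray] = {}
        for name in structure.names:
            alpha = np.asarray(concentrations[name], dtype=float)
            expected = (structure.n_rows(name), len(structure[name].states))
            if alpha.shape != expected:
                raise ConfigurationError(
                    f"concentrations for {name!r} have shape {alpha.shape}, expected {expected}"
                )
            if (alpha < prior_strength - 1e-12).any():
                raise ConfigurationError(
                    f"concentration below prior strength for {name!r}"
                )
            self.concentrations[name] = alpha

    # -- summaries ----------------------------------------------------------------

    def posterior_mean(self) -> dict[str, np.ndarray]:
        """Plug-in CPTs: each row normalised to its concentration total."""
        return {
            name: alpha / alpha.sum(axis=1, keepdims=True)
            for name, alpha in self.concentrations.items()
        }

    def cpd_summary(self, variable: str, parent_config: Mapping[str, str],
                    state: str) -> CredibleSummary:
        """Exact equal-tailed 95% summary of one CPT entry.

        The marginal posterior of entry ``state`` in a Dirichlet row with
        concentrations ``alpha`` is Beta(``alpha_state``, ``alpha_total -
        alpha_state``); quantiles are computed exactly, no sampling.
        """
        row = self.structure.row_index(variable, parent_config)
        s = self.structure.state_index(variable, state)
        alpha = self.concentrations[variable][row]
        a = alpha[s]
        b = alpha.sum() - a
        q025, median, q975 = beta_dist.ppf([0.025, 0.5, 0.975], a, b)
        return CredibleSummary(float(q025), float(median), float(q975))

    # -- posterior sampling -------------------------------------------------------

    def sample_parameters(self, n_samples: int = 1,
                          seed: int | np.random.Generator = 0) -> dict[str, np.ndarray]:
        """Draw CPT parameter sets from the posterior.

        Every CPT row is drawn independently from its Dirichlet posterior
        (the exact joint posterior under the conjugate model).  Returns one
        array of shape ``(n_samples, n_rows, n_states)`` per variable;
        identical seeds give identical draws.
        """
        if n_samples < 1:
            raise ConfigurationError("n_samples must be >= 1")
        rng = np.random.default_rng(seed)
        draws: dict[str, np.ndarray] = {}
        for name in self.structure.names:
            alpha = self.concentrations[name]
            g = rng.gamma(shape=alpha[None, :, :], size=(n_samples, *alpha.shape))
            draws[name] = g / g.sum(axis=2, keepdims=True)
        return draws

    # -- plain-text (de)serialisation ---------------------------------------------

    def to_dict(self) -> dict:
        return {
            "structure": self.structure.to_dict(),
            "prior_strength": self.prior_strength,
            "concentrations": {
                name: [[float(x) for x in row] for row in alpha]
                for name, alpha in self.concentrations.items()
            },
        }

    def save(self, path: str | Path) -> None:
        """Serialise as a human-auditable YAML document of concentrations."""
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "FittedModel":
        d = yaml.safe_load(Path(path).read_text())
        structure = NetworkStructure.from_dict(d["structure"])
        conc = {name: np.asarray(rows, dtype=float) for name, rows in d["concentrations"].items()}
        return cls(structure, conc, prior_strength=float(d["prior_strength"]))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FittedModel):
            return NotImplemented
        return (
            self.structure == other.structure
            and self.prior_strength == other.prior_strength
            and all(np.array_equal(self.concentrations[n], other.concentrations[n])
                    for n in self.structure.names)
        )


def fit(counts: Mapping[str, CountTable] | Sequence[CountTable],
        structure: NetworkStructure, prior_strength: float = 1.0) -> FittedModel:
    """Conjugate update: posterior concentration = prior_strength + count.

    ``counts`` must cover every variable of the structure; a missing table
    raises :class:`ConfigurationError`.
    """
    if not isinstance(counts, Mapping):
        counts = {t.variable: t for t in counts}
    conc: dict[str, np.ndarray] = {}
    for name in structure.names:
        if name not in counts:
            raise ConfigurationError(f"no count table supplied for variable {name!r}")
        table = counts[name]
        if table.states != structure[name].states or \
                table.parent_configs != structure.parent_configs(name):
            raise ConfigurationError(
                f"count table for {name!r} does not match the structure's rows/states"
            )
        conc[name] = prior_strength + table.counts.astype(float)
    return FittedModel(structure, conc, prior_strength=prior_strength)
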