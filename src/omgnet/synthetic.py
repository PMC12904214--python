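"""Synthetic suspected-OMG cohorts by ancestral sampling.

Cohorts are drawn from explicit CPT parameter vectors — typically the
plug-in posterior means of a fitted model, or any fixed vectors — by
sampling each variable in topological order given its parents.  Observed
values are then masked independently per variable at configurable rates
(missing completely at random); the disease outcome is never masked, since
generated cohorts stand in for training data whose diagnosis is always
adjudicated.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np

from .dataio import PatientRecord
from .errors import ConfigurationError
from .model import FittedModel
from .network import NetworkStructure

__all__ = ["SyntheticConfig", "generate", "generate_from_model"]


@dataclass(frozen=True)
class SyntheticConfig:
    """How many records to draw, which variables go missing how often, and the seed."""

    n_records: int
    missing_rates: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 0:
            raise ConfigurationError("n_records must be non-negative")
        for name, rate in self.missing_rates.items():
            if not 0 <= rate <= 1:
                raise ConfigurationError(f"missing rate for {name!r} outside [0, 1]")


def generate(config: SyntheticConfig, structure: NetworkStructure,
             params: Mapping[str, np.ndarray]) -> list[PatientRecord]:
    """Ancestral sampling then per-variable MCAR masking; seeded and reproducible.

    ``params`` maps each variable to a ``(n_rows, n_states)`` array of
    probability vectors (rows in the structure's parent-configuration order).
    """
    outcome = structure.outcome
    if config.missing_rates.get(outcome, 0.0) != 0.0:
        raise ConfigurationError(f"the outcome {outcome!r} may not be masked")
    rng = np.random.default_rng(config.seed)
    n = config.n_records
    drawn: dict[str, np.ndarray] = {}
    for name in structure.order:
        spec = structure[name]
        p = np.asarray(params[name], dtype=float)
        if p.shape != (structure.n_rows(name), len(spec.states)) or \
                not np.allclose(p.sum(axis=1), 1.0, atol=1e-8) or (p < 0).any():
            raise ConfigurationError(f"invalid probability table for {name!r}")
        rows = np.zeros(n, dtype=np.int64)
        for parent in spec.parents:
            rows = rows * len(structure[parent].states) + drawn[parent]
        cum = np.cumsum(p[rows], axis=1)
        u = rng.random(n)
        drawn[name] = (u[:, None] > cum).sum(axis=1).astype(np.int64)
    masks = {
        name: rng.random(n) < rate
        for name, rate in config.missing_rates.items() if name in structure
    }
    records = []
    for i in range(n):
        values: dict[str, str | None] = {}
        for name in structure.names:
            if name in masks and masks[name][i]:
                values[name] = None
            else:
                values[name] = structure[name].states[drawn[name][i]]
        records.append(PatientRecord(values))
    return records


def generate_from_model(config: SyntheticConfig, model: FittedModel) -> list[PatientRecord]:
    """Generate from a fitted model's plug-in posterior-mean CPTs."""
    return generate(config, model.structure, model.posterior_mean())
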