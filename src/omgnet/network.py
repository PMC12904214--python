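"""Categorical variables and the directed acyclic structure relating them.

A :class:`NetworkStructure` is the qualitative half of a discrete Bayesian
network: each variable carries an ordered list of states and an ordered list
of parents, and the joint distribution factorises as
``p(x_1, ..., x_m) = prod_i p(x_i | pa(x_i))``.  The quantitative half (one
conditional probability table per variable) lives in :mod:`omgnet.model`.

The default structure shipped with the package describes a suspected
ocular-myasthenia-gravis (OMG) work-up: age and sex are roots, disease
status depends on sex, acetylcholine-receptor serology depends on disease
status and age, and each remaining clinical sign or ancillary test depends
on disease status alone.
"""

from __future__ import annotations

import itertools
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from importlib import resources
from math import prod
from pathlib import Path

import yaml

from .errors import ConfigurationError, SchemaError

__all__ = ["VariableSpec", "NetworkStructure", "default_structure"]


@dataclass(frozen=True)
class VariableSpec:
    """One categorical variable: its name, ordered states, ordered parents."""

    name: str
    states: tuple[str, ...]
    parents: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        object.__setattr__(self, "parents", tuple(self.parents))
        if len(self.states) < 2 or len(set(self.states)) != len(self.states):
            raise ConfigurationError(
                f"variable {self.name!r} needs >=2 distinct states, got {self.states}"
            )
        if len(set(self.parents)) != len(self.parents):
            raise ConfigurationError(f"variable {self.name!r} has duplicate parents")
        if self.name in self.parents:
            raise ConfigurationError(f"variable {self.name!r} cannot be its own parent")


class NetworkStructure:
    """An acyclic parent structure over a set of categorical variables.

    Parameters
    ----------
    variables:
        The variable specs, in the order used for tabular (CSV) columns.
        The topological order used for sampling and inference is computed
        independently and exposed as :attr:`order`.
    outcome:
        Name of the outcome variable (default ``"omg"`` when present,
        otherwise the last declared variable).
    """

    def __init__(self, variables: Sequence[VariableSpec], outcome: str | None = None):
        specs = list(variables)
        names = [v.name for v in specs]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate variable names in structure")
        self._vars: dict[str, VariableSpec] = {v.name: v for v in specs}
        for v in specs:
            for p in v.parents:
                if p not in self._vars:
                    raise ConfigurationError(
                        f"variable {v.name!r} names undeclared parent {p!r}"
                    )
        self.order: tuple[str, ...] = self._toposort()
        if outcome is None:
            outcome = "omg" if "omg" in self._vars else names[-1]
        if outcome not in self._vars:
            raise ConfigurationError(f"outcome variable {outcome!r} not declared")
        self.outcome = outcome

    # -- basic container protocol -------------------------------------------------

    @property
    def names(self) -> tuple[str, ...]:
        """Variable names in declaration (column) order."""
        return tuple(self._vars)

    def __contains__(self, name: object) -> bool:
        return name in self._vars

    def __iter__(self):
        return iter(self._vars.values())

    def __getitem__(self, name: str) -> VariableSpec:
        try:
            return self._vars[name]
        except KeyError:
            raise SchemaError(f"unknown variable {name!r}") from None

    def __len__(self) -> int:
        return len(self._vars)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, NetworkStructure)
            and list(self._vars.values()) == list(other._vars.values())
            and self.outcome == other.outcome
        )

    # -- graph queries ------------------------------------------------------------

    def _toposort(self) -> tuple[str, ...]:
        # Kahn's algorithm; raises on any directed cycle.
        indeg = {n: len(v.parents) for n, v in self._vars.items()}
        children: dict[str, list[str]] = {n: [] for n in self._vars}
        for v in self._vars.values():
            for p in v.parents:
                children[p].append(v.name)
        ready = [n for n, d in indeg.items() if d == 0]
        out: list[str] = []
        while ready:
            n = ready.pop()
            out.append(n)
            for c in children[n]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    ready.append(c)
        if len(out) != len(self._vars):
            raise ConfigurationError("parent structure contains a cycle")
        return tuple(out)

    def ancestral_closure(self, names: Iterable[str]) -> frozenset[str]:
        """The given variables together with all their ancestors."""
        seen: set[str] = set()
        stack = [self[n].name for n in names]
        while stack:
            n = stack.pop()
            if n not in seen:
                seen.add(n)
                stack.extend(self[n].parents)
        return frozenset(seen)

    # -- CPT row indexing ---------------------------------------------------------

    def parent_configs(self, name: str) -> tuple[tuple[str, ...], ...]:
        """All parent-state configurations of ``name``, in row order."""
        v = self[name]
        return tuple(itertools.product(*(self[p].states for p in v.parents)))

    def n_rows(self, name: str) -> int:
        v = self[name]
        return prod(len(self[p].states) for p in v.parents)

    def state_index(self, name: str, state: str) -> int:
        v = self[name]
        try:
            return v.states.index(state)
        except ValueError:
            raise SchemaError(
                f"state {state!r} not declared for variable {name!r}; "
                f"expected one of {list(v.states)}"
            ) from None

    def row_index(self, name: str, assignment: Mapping[str, str]) -> int:
        """Mixed-radix index of the CPT row selected by the parent states."""
        v = self[name]
        idx = 0
        for p in v.parents:
            if p not in assignment:
                raise SchemaError(f"parent {p!r} of {name!r} is unassigned")
            idx = idx * len(self[p].states) + self.state_index(p, assignment[p])
        return idx

    def row_config(self, name: str, row: int) -> dict[str, str]:
        """Inverse of :meth:`row_index`: the parent assignment of a row."""
        v = self[name]
        config = self.parent_configs(name)[row]
        return dict(zip(v.parents, config))

    # -- (de)serialisation --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "variables": [
                {"name": v.name, "states": list(v.states), "parents": list(v.parents)}
                for v in self._vars.values()
            ],
            "outcome": self.outcome,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "NetworkStructure":
        specs = [
            VariableSpec(
                name=str(v["name"]),
                states=tuple(str(s) for s in v["states"]),
                parents=tuple(str(p) for p in v.get("parents", ())),
            )
            for v in d["variables"]
        ]
        return cls(specs, outcome=d.get("outcome"))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NetworkStructure":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_structure() -> NetworkStructure:
    """The packaged suspected-OMG network (12 variables)."""
    text = resources.files("omgnet.data").joinpath("network.yaml").read_text()
    return NetworkStructure.from_dict(yaml.safe_load(text))
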