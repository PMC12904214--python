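"""Patient records: binning of continuous inputs and CSV input/output.

The on-disk schema is one row per patient and one column per variable, in
the structure's declared column order (``age, sex, diplopia, ptosis, achr,
upgaze, ice, besinger, edrophonium, rns, sfemg, omg``), with a configurable
missing-value marker (default ``"NA"``).  Age in years and a raw
Besinger/QMG severity score are accepted in place of their binned category
labels and are binned on read.
"""

from __future__ import annotations

from collections.abc import Iterator, Mapping, Sequence
from pathlib import Path

import pandas as pd

from .errors import SchemaError
from .network import NetworkStructure

__all__ = [
    "PatientRecord",
    "bin_age",
    "bin_besinger",
    "read_records",
    "write_records",
    "DEFAULT_MISSING",
]

DEFAULT_MISSING = "NA"

# Right-closed bins. Age labels follow the adult study population (youngest
# participants were 18); the bin itself accepts any age in (0, 50].
_AGE_EDGES = ((0.0, 50.0, "18-50"), (50.0, 70.0, "50-70"), (70.0, 120.0, "70+"))
_BESINGER_EDGES = ((-1.0, 1.0, "-1-1"), (1.0, 4.0, "1-4"), (4.0, 8.0, "4-8"), (8.0, 24.0, "8-24"))


def bin_age(years: float) -> str:
    """Map an age in years to its category: (0,50] → ``18-50``, (50,70] → ``50-70``, (70,120] → ``70+``."""
    if not 0 < years <= 120:
        raise SchemaError(f"age {years!r} outside (0, 120]")
    for lo, hi, label in _AGE_EDGES:
        if lo < years <= hi:
            return label
    raise AssertionError("unreachable: bins cover (0, 120]")


def bin_besinger(score: float) -> str:
    """Map a raw Besinger/QMG score to its category: [-1,1], (1,4], (4,8], (8,24]."""
    if not -1 <= score <= 24:
        raise SchemaError(f"Besinger/QMG score {score!r} outside [-1, 24]")
    if score <= 1:
        return "-1-1"
    for lo, hi, label in _BESINGER_EDGES[1:]:
        if lo < score <= hi:
            return label
    raise AssertionError("unreachable: bins cover [-1, 24]")


_RAW_BINNERS = {"age": bin_age, "besinger": bin_besinger}


class PatientRecord(Mapping[str, str]):
    """An immutable complete-or-partial assignment of states to variables.

    Only observed variables are stored; ``record.get(name)`` returns ``None``
    for a missing one.
    """

    __slots__ = ("_values",)

    def __init__(self, values: Mapping[str, str | None]):
        self._values: dict[str, str] = {k: v for k, v in values.items() if v is not None}

    def __getitem__(self, key: str) -> str:
        return self._values[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._values)

    def __len__(self) -> int:
        return len(self._values)

    def observed(self, *names: str) -> bool:
        """True when every named variable has a value in this record."""
        return all(n in self._values for n in names)

    def __repr__(self) -> str:
        body = ", ".join(f"{k}={v}" for k, v in self._values.items())
        return f"PatientRecord({body})"

    def __eq__(self, other: object) -> bool:
        if isinstance(other, PatientRecord):
            return self._values == other._values
        return NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self._values.items()))


def coerce_cell(structure: NetworkStructure, variable: str, raw: str,
                missing: str = DEFAULT_MISSING) -> str | None:
    """Interpret one CSV cell: missing marker, state label, or raw number to bin."""
    raw = raw.strip()
    if raw == missing or raw == "":
        return None
    spec = structure[variable]
    if raw in spec.states:
        return raw
    if variable in _RAW_BINNERS:
        try:
            value = float(raw)
        except ValueError:
            pass
        else:
            return _RAW_BINNERS[variable](value)
    raise SchemaError(
        f"cannot interpret {raw!r} as a state of {variable!r} "
        f"(expected one of {list(spec.states)} or {missing!r})"
    )


def read_records(path: str | Path, structure: NetworkStructure,
                 missing: str = DEFAULT_MISSING,
                 ignore_unknown: bool = False) -> list[PatientRecord]:
    """Read patient records from a CSV file.

    Unknown columns raise :class:`SchemaError` unless ``ignore_unknown``;
    declared variables absent from the file are treated as entirely missing.
    Cell errors report the offending row and column.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    unknown = [c for c in df.columns if c not in structure]
    if unknown and not ignore_unknown:
        raise SchemaError(f"unknown column(s) {unknown} in {path}")
    columns = [c for c in df.columns if c in structure]
    records: list[PatientRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        values: dict[str, str | None] = {}
        for col, raw in zip(df.columns, row):
            if col not in columns:
                continue
            try:
                values[col] = coerce_cell(structure, col, str(raw), missing=missing)
            except SchemaError as exc:
                raise SchemaError(f"row {i + 2}, column {col!r}: {exc}") from None
        records.append(PatientRecord(values))
    return records


def records_frame(records: Sequence[PatientRecord], structure: NetworkStructure,
                  missing: str = DEFAULT_MISSING) -> pd.DataFrame:
    """Records as a DataFrame in schema column order, missing marker filled in."""
    return pd.DataFrame(
        [{name: r.get(name, missing) for name in structure.names} for r in records],
        columns=list(structure.names),
    )


def write_records(records: Sequence[PatientRecord], path: str | Path,
                  structure: NetworkStructure, missing: str = DEFAULT_MISSING) -> None:
    """Write records as CSV; inverse of :func:`read_records`."""
    records_frame(records, structure, missing=missing).to_csv(path, index=False)
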