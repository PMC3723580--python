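"""Omics expression tables and the name-to-ID converter.

An :class:`OmicsTable` is one omics layer: molecule IDs down the rows,
experimental conditions (treatment groups or time points, in upload
order) across the columns, real-valued expression / concentration /
intensity measurements in the cells. Tables are uploaded as CSV with
the ID in the first column; the empty string and ``NA`` denote missing
values, anything else non-numeric is a hard parse error.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ids import Layer, MoleculeID

MISSING_TOKENS = frozenset({"", "NA"})


class OmicsTableError(ValueError):
    """Raised on malformed omics tables."""


@dataclass
class OmicsTable:
    """One omics layer: ids x conditions matrix of measurements.

    ``data`` is a float DataFrame indexed by raw ID strings with the
    condition labels as columns (NaN marks a missing cell); ``layer``
    fixes the identifier namespace for every row.
    """

    layer: Layer
    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.layer = Layer(self.layer)
        if self.data.shape[1] < 2:
            raise OmicsTableError(
                f"omics table needs at least 2 condition columns, got {self.data.shape[1]}"
            )
        idx = self.data.index.astype(str)
        dup = idx[idx.duplicated()].unique().tolist()
        if dup:
            raise OmicsTableError(f"duplicate molecule IDs: {', '.join(dup)}")
        self.data = self.data.astype(float)
        self.data.index = idx
        self.data.columns = [str(c) for c in self.data.columns]
        for v in idx:
            MoleculeID(self.layer.namespace, v)  # validates the ID syntax

    @property
    def ids(self) -> list[MoleculeID]:
        ns = self.layer.namespace
        return [MoleculeID(ns, v) for v in self.data.index]

    @property
    def conditions(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def __len__(self) -> int:
        return self.data.shape[0]


def read_omics_csv(path: str | Path, layer: Layer | str) -> OmicsTable:
    """Parse one omics CSV into a validated :class:`OmicsTable`.

    The first header cell names the ID column; the remaining header
    cells are condition labels, preserved in file order. Cells equal to
    ``""`` or ``"NA"`` parse as missing; any other non-numeric cell is
    rejected with its row and column location.
    """
    layer = Layer(layer)
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise OmicsTableError(f"{path}: empty file")
    header = rows[0]
    if len(header) < 3:
        raise OmicsTableError(
            f"{path}: need an ID column plus at least 2 condition columns, "
            f"got {len(header)} columns"
        )
    conditions = [c.strip() for c in header[1:]]
    ids: list[str] = []
    seen: dict[str, int] = {}
    values: list[list[float]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if not row or all(cell.strip() == "" for cell in row):
            continue
        if len(row) != len(header):
            raise OmicsTableError(
                f"{path}:{lineno}: expected {len(header)} cells, got {len(row)}"
            )
        mol = row[0].strip()
        if mol in seen:
            raise OmicsTableError(
                f"{path}: duplicate ID {mol!r} on rows {seen[mol]} and {lineno}"
            )
        seen[mol] = lineno
        parsed: list[float] = []
        for col, cell in zip(conditions, row[1:]):
            cell = cell.strip()
            if cell in MISSING_TOKENS:
                parsed.append(np.nan)
                continue
            try:
                parsed.append(float(cell))
            except ValueError:
                raise OmicsTableError(
                    f"{path}:{lineno}: non-numeric value {cell!r} in column {col!r}"
                ) from None
        ids.append(mol)
        values.append(parsed)
    if not ids:
        raise OmicsTableError(f"{path}: no data rows")
    frame = pd.DataFrame(values, index=ids, columns=conditions, dtype=float)
    return OmicsTable(layer, frame)


def write_omics_csv(table: OmicsTable, path: str | Path) -> None:
    """Write an :class:`OmicsTable` back to CSV.

    Finite values are written with ``repr`` so a read/write cycle is
    bit-identical; missing cells are written as the empty string.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", *table.conditions])
        for mol, row in zip(table.data.index, table.data.to_numpy()):
            writer.writerow(
                [mol, *("" if np.isnan(v) else repr(float(v)) for v in row)]
            )


class MatchStatus(str, Enum):
    UNIQUE = "unique"
    AMBIGUOUS = "ambiguous"
    UNMAPPED = "unmapped"


@dataclass(frozen=True)
class NameMatch:
    name: str
    ids: tuple[MoleculeID, ...]
    status: MatchStatus


@dataclass
class NameMap:
    """Case-insensitive name -> molecule-ID map; ambiguity is preserved."""

    entries: Iterable[tuple[str, MoleculeID]] = field(default_factory=list)

    def __post_init__(self) -> None:
        table: dict[str, set[MoleculeID]] = {}
        for name, mol in self.entries:
            table.setdefault(name.casefold(), set()).add(mol)
        self._table = table

    def lookup(self, name: str) -> tuple[MoleculeID, ...]:
        return tuple(sorted(self._table.get(name.casefold(), ())))

    def __len__(self) -> int:
        return len(self._table)


def convert_names(names: Sequence[str], name_map: NameMap) -> list[NameMatch]:
    """Resolve molecule names to IDs by case-insensitive exact match.

    Every input name yields exactly one record; a name mapping to
    several IDs is flagged ambiguous with all candidates, an unknown
    name is flagged unmapped (never an error).
    """
    out: list[NameMatch] = []
    for name in names:
        ids = name_map.lookup(name)
        if not ids:
            status = MatchStatus.UNMAPPED
        elif len(ids) == 1:
            status = MatchStatus.UNIQUE
        else:
            status = MatchStatus.AMBIGUOUS
        out.append(NameMatch(name, ids, status))
    return out
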