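"""Species tables in the Malacolog-style tab-separated dialect.

A table holds one row per species (or subspecies, kept as independent
records): taxon name, genus, maximum recorded shell length in mm, and the
shallowest and deepest recorded depths in m.  The analysis variable used
downstream is ``log10(shell_length_mm)``; regression slopes and all
p-values are invariant to the choice of log base, so base 10 is adopted to
match malacological convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from bathyrule.errors import EmptyTableError, SchemaError

logger = logging.getLogger(__name__)

#: Logical field -> default column header of the tab-separated dialect.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "taxon_name": "taxon",
    "genus": "genus",
    "shell_length_mm": "length_mm",
    "depth_min_m": "depth_min_m",
    "depth_max_m": "depth_max_m",
}

_NUMERIC_FIELDS = ("shell_length_mm", "depth_min_m", "depth_max_m")


@dataclass(frozen=True)
class SpeciesRecord:
    """One taxon with its size and depth-range observables.

    Invariants: ``shell_length_mm > 0`` and
    ``0 <= depth_min_m <= depth_max_m``.
    """

    taxon_name: str
    genus: str
    shell_length_mm: float
    depth_min_m: float
    depth_max_m: float

    def __post_init__(self) -> None:
        if not self.taxon_name:
            raise ValueError("taxon_name must be non-empty")
        if not self.genus:
            raise ValueError("genus must be non-empty")
        if not self.shell_length_mm > 0:
            raise ValueError(f"{self.taxon_name}: shell_length_mm must be > 0")
        if self.depth_min_m < 0:
            raise ValueError(f"{self.taxon_name}: depth_min_m must be >= 0")
        if self.depth_min_m > self.depth_max_m:
            raise ValueError(f"{self.taxon_name}: inverted depth range")

    @property
    def log_size(self) -> float:
        """log10 of the maximum shell length (mm)."""
        return math.log10(self.shell_length_mm)

    @property
    def depth_midpoint_m(self) -> float:
        """Mean of the shallowest and deepest recorded depths (m)."""
        return (self.depth_min_m + self.depth_max_m) / 2.0


@dataclass
class SpeciesTable:
    """An ordered collection of unique-named species records."""

    records: list[SpeciesRecord] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        names = [r.taxon_name for r in self.records]
        if len(set(names)) != len(names):
            raise ValueError("duplicate taxon names in table")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "taxon_name": [r.taxon_name for r in self.records],
                "genus": [r.genus for r in self.records],
                "shell_length_mm": [r.shell_length_mm for r in self.records],
                "depth_min_m": [r.depth_min_m for r in self.records],
                "depth_max_m": [r.depth_max_m for r in self.records],
            }
        )


def read_species_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> SpeciesTable:
    """Read a tab-separated species table, dropping and counting bad rows.

    ``column_map`` maps the five logical fields (``taxon_name``, ``genus``,
    ``shell_length_mm``, ``depth_min_m``, ``depth_max_m``) to the column
    headers actually present in the file.  Lines starting with ``#`` are
    ignored.  Rows missing any field, failing numeric parsing, or violating
    a record invariant are dropped with a per-reason count; duplicate taxon
    names keep the first occurrence.

    Raises
    ------
    SchemaError
        If the header lacks a mapped column.
    EmptyTableError
        If no valid rows remain.
    """
    path = Path(path)
    cmap = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)

    missing = [col for col in cmap.values() if col not in df.columns]
    if missing:
        raise SchemaError(f"{path}: header is missing mapped column(s) {missing}")

    drop_reasons: dict[str, int] = {}

    def _drop(reason: str) -> None:
        drop_reasons[reason] = drop_reasons.get(reason, 0) + 1

    records: list[SpeciesRecord] = []
    seen: set[str] = set()
    n_read = 0
    for rowd in df.to_dict("records"):
        n_read += 1
        raw = {logical: rowd[cmap[logical]] for logical in cmap}
        if any(str(raw[f]).strip() == "" for f in cmap):
            _drop("missing field")
            continue
        try:
            values = {f: float(raw[f]) for f in _NUMERIC_FIELDS}
        except ValueError:
            _drop("non-numeric value")
            continue
        name = str(raw["taxon_name"]).strip()
        if name in seen:
            _drop("duplicate taxon name")
            logger.warning("duplicate taxon %r: keeping first occurrence", name)
            continue
        try:
            rec = SpeciesRecord(
                taxon_name=name,
                genus=str(raw["genus"]).strip(),
                **values,
            )
        except ValueError as exc:
            if "inverted" in str(exc):
                _drop("inverted depth range")
            elif "shell_length" in str(exc):
                _drop("non-positive shell length")
            else:
                _drop("invalid record")
            continue
        seen.add(name)
        records.append(rec)

    n_dropped = n_read - len(records)
    logger.info(
        "%s: read %d rows, retained %d, dropped %d (%s)",
        path,
        n_read,
        len(records),
        n_dropped,
        ", ".join(f"{k}: {v}" for k, v in sorted(drop_reasons.items())) or "none",
    )
    if not records:
        raise EmptyTableError(f"{path}: no valid species rows retained")
    return SpeciesTable(records=records, source=str(path))


def write_species_table(table: SpeciesTable, path: str | Path) -> None:
    """Write ``table`` in the same tab-separated dialect (round-trip safe).

    Numeric fields are written with ``repr`` so a write/read cycle is the
    identity at full float precision, and output bytes are stable across
    repeated writes.
    """
    path = Path(path)
    headers = [DEFAULT_COLUMN_MAP[f] for f in DEFAULT_COLUMN_MAP]
    lines = ["\t".join(headers)]
    for r in table.records:
        lines.append(
            "\t".join(
                [
                    r.taxon_name,
                    r.genus,
                    repr(r.shell_length_mm),
                    repr(r.depth_min_m),
                    repr(r.depth_max_m),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def table_from_records(records: Iterable[SpeciesRecord], source: str = "") -> SpeciesTable:
    return SpeciesTable(records=list(records), source=source)
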