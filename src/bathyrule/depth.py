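"""Deep / shallow / excluded classification of species by recorded depth.

Two schemes are supported.  The *midpoint* scheme splits on the depth-range
midpoint at a boundary (default 200 m, the average Atlantic shelf limit and
photic-zone floor): midpoint above the boundary is deep, everything else
shallow, nothing excluded.  The *strict* scheme calls a species shallow only
if it was never recorded below the boundary, deep only if it was never
recorded above a deep cutoff (200/400/600/800 m), and excludes the rest.

Boundary conventions: shallow uses ``depth_max_m <= boundary`` and deep uses
``depth_min_m > deep_cutoff``, so a species sitting exactly on the boundary
is shallow and never in both categories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

from bathyrule.tables import SpeciesRecord, SpeciesTable

Category = Literal["deep", "shallow", "excluded"]
ExclusionMode = Literal["range_min_exceeds", "range_max_exceeds"]


@dataclass(frozen=True)
class DepthRule:
    """Parameters of a classification scheme.

    ``deep_cutoff_m`` applies to the strict scheme only and must be at least
    ``boundary_m``; it defaults to the boundary itself.
    """

    scheme: Literal["midpoint", "strict"] = "strict"
    boundary_m: float = 200.0
    deep_cutoff_m: float | None = None

    def __post_init__(self) -> None:
        if self.scheme not in ("midpoint", "strict"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.boundary_m <= 0:
            raise ValueError("boundary_m must be positive")
        if self.deep_cutoff_m is None:
            object.__setattr__(self, "deep_cutoff_m", self.boundary_m)
        if self.scheme == "strict" and self.deep_cutoff_m < self.boundary_m:
            raise ValueError("strict scheme requires deep_cutoff_m >= boundary_m")


@dataclass(frozen=True)
class DepthAssignment:
    taxon_name: str
    category: Category
    rule: DepthRule


def depth_midpoint(record: SpeciesRecord) -> float:
    """Mean of the shallowest and deepest recorded depths (m)."""
    return record.depth_midpoint_m


def classify(record: SpeciesRecord, rule: DepthRule) -> DepthAssignment:
    """Assign one species to deep / shallow / excluded under ``rule``."""
    if rule.scheme == "midpoint":
        category: Category = "deep" if depth_midpoint(record) > rule.boundary_m else "shallow"
    else:
        if record.depth_max_m <= rule.boundary_m:
            category = "shallow"
        elif record.depth_min_m > rule.deep_cutoff_m:
            category = "deep"
        else:
            category = "excluded"
    return DepthAssignment(taxon_name=record.taxon_name, category=category, rule=rule)


def classify_table(table: SpeciesTable, rule: DepthRule) -> list[DepthAssignment]:
    return [classify(r, rule) for r in table]


def exclude_by_depth(
    table: SpeciesTable,
    mode: ExclusionMode,
    threshold_m: float,
) -> tuple[SpeciesTable, int]:
    """Drop abyssal/bathypelagic species by depth-range threshold.

    ``range_min_exceeds`` drops species whose whole range is below the
    threshold (``depth_min_m > threshold``); ``range_max_exceeds`` drops
    species whose range is even partly below it (``depth_max_m >
    threshold``).  Returns the filtered table and the number dropped.
    """
    if threshold_m <= 0:
        raise ValueError("threshold_m must be positive")
    if mode == "range_min_exceeds":
        keep = [r for r in table if r.depth_min_m <= threshold_m]
    elif mode == "range_max_exceeds":
        keep = [r for r in table if r.depth_max_m <= threshold_m]
    else:
        raise ValueError(f"unknown exclusion mode {mode!r}")
    filtered = SpeciesTable(records=keep, source=table.source)
    return filtered, len(table) - len(keep)


def records_excluded_by_depth(
    records: Iterable[SpeciesRecord],
    mode: ExclusionMode,
    threshold_m: float,
) -> list[SpeciesRecord]:
    """The subset of ``records`` that the depth filter would drop."""
    if mode == "range_min_exceeds":
        return [r for r in records if r.depth_min_m > threshold_m]
    if mode == "range_max_exceeds":
        return [r for r in records if r.depth_max_m > threshold_m]
    raise ValueError(f"unknown exclusion mode {mode!r}")
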