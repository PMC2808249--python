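"""Genus-level pairing of deep and shallow congeners.

Each genus that contains both deep and shallow species contributes one data
point: a shallow log-size estimate ``x`` and a deep log-size estimate ``y``
(means of log10 shell lengths, taken after the log transform to avoid
bias).  Three balancing schemes control which species enter the means:

``all_means``
    every classified congener;
``equalized``
    equal deep and shallow counts per genus, discarding from the larger
    side the species that *reduce* the deep-minus-shallow midpoint-depth
    contrast (drop the deepest-midpoint shallow species, or the
    shallowest-midpoint deep species);
``single_pair``
    the one deep / one shallow pair with maximal midpoint-depth difference.

Equalization exists because most genera hold fewer deep than shallow
species, and unequal counts alone shrink the deep sample variance — which a
variance-ratio slope would misread as size convergence.

Midpoint ties are broken deterministically: smaller shell length first,
then lexicographic taxon name.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import fmean
from typing import Iterable, Literal, Mapping, Sequence

from bathyrule.depth import DepthAssignment
from bathyrule.tables import SpeciesRecord, SpeciesTable

PairingScheme = Literal["all_means", "equalized", "single_pair"]

#: genus -> (deep species, shallow species)
GenusGroups = dict[str, tuple[list[SpeciesRecord], list[SpeciesRecord]]]


@dataclass(frozen=True)
class GenusPair:
    """One genus's (shallow x, deep y) log10-size point and its provenance."""

    genus: str
    x_shallow_logsize: float
    y_deep_logsize: float
    shallow_species: tuple[SpeciesRecord, ...]
    deep_species: tuple[SpeciesRecord, ...]
    scheme: PairingScheme

    def __post_init__(self) -> None:
        if not self.shallow_species or not self.deep_species:
            raise ValueError(f"{self.genus}: both species sets must be non-empty")
        if self.scheme in ("equalized", "single_pair") and len(self.shallow_species) != len(
            self.deep_species
        ):
            raise ValueError(f"{self.genus}: {self.scheme} pairing requires equal counts")


def _tiebreak_key(record: SpeciesRecord) -> tuple[float, str]:
    return (record.shell_length_mm, record.taxon_name)


def sort_for_selection(records: Iterable[SpeciesRecord]) -> list[SpeciesRecord]:
    """Canonical species order used to break midpoint ties deterministically."""
    return sorted(records, key=_tiebreak_key)


def group_into_genera(
    table: SpeciesTable,
    assignments: Sequence[DepthAssignment],
) -> GenusGroups:
    """Split classified species by genus, keeping two-sided genera only.

    Species in the ``excluded`` category are dropped; a genus appears in the
    result iff it retains at least one deep and one shallow species.
    """
    by_name = {a.taxon_name: a.category for a in assignments}
    missing = [r.taxon_name for r in table if r.taxon_name not in by_name]
    if missing:
        raise ValueError(f"assignments do not cover the table (e.g. {missing[0]!r})")
    groups: GenusGroups = {}
    for record in table:
        category = by_name[record.taxon_name]
        if category == "excluded":
            continue
        deep, shallow = groups.setdefault(record.genus, ([], []))
        (deep if category == "deep" else shallow).append(record)
    return {g: (d, s) for g, (d, s) in groups.items() if d and s}


def pair_all_means(
    deep: Sequence[SpeciesRecord],
    shallow: Sequence[SpeciesRecord],
    genus: str | None = None,
    scheme: PairingScheme = "all_means",
) -> GenusPair:
    """Mean log10 size over all shallow (x) and all deep (y) congeners."""
    if not deep or not shallow:
        raise ValueError("both species sets must be non-empty")
    return GenusPair(
        genus=genus if genus is not None else deep[0].genus,
        x_shallow_logsize=fmean(r.log_size for r in shallow),
        y_deep_logsize=fmean(r.log_size for r in deep),
        shallow_species=tuple(shallow),
        deep_species=tuple(deep),
        scheme=scheme,
    )


def equalize_counts(
    deep: Sequence[SpeciesRecord],
    shallow: Sequence[SpeciesRecord],
) -> tuple[list[SpeciesRecord], list[SpeciesRecord]]:
    """Trim the larger side to equal counts, maximizing the midpoint contrast.

    When shallow species outnumber deep ones, the shallow species with the
    deepest range midpoints are removed (the shallowest-midpoint shallow
    species are kept); symmetrically, surplus deep species with the
    shallowest midpoints are removed.  This greedy rule maximizes
    ``mean(deep midpoints) - mean(shallow midpoints)`` over all equal-size
    subset pairs, because the objective is separable in the two sides.
    """
    if not deep or not shallow:
        raise ValueError("both species sets must be non-empty")
    k = min(len(deep), len(shallow))
    deep_sorted = sorted(sort_for_selection(deep), key=lambda r: -r.depth_midpoint_m)
    shallow_sorted = sorted(sort_for_selection(shallow), key=lambda r: r.depth_midpoint_m)
    return deep_sorted[:k], shallow_sorted[:k]


def select_single_pair(
    deep: Sequence[SpeciesRecord],
    shallow: Sequence[SpeciesRecord],
) -> tuple[SpeciesRecord, SpeciesRecord]:
    """The (deep, shallow) pair with maximal midpoint-depth difference.

    Equivalent to taking the deepest-midpoint deep species and the
    shallowest-midpoint shallow species, since the difference separates.
    """
    deep_sel, shallow_sel = equalize_counts(deep, shallow)
    deep_best = deep_sel[0]
    shallow_best = shallow_sel[0]
    return deep_best, shallow_best


def filter_min_counts(
    groups: GenusGroups,
    min_deep: int = 2,
    min_shallow: int = 2,
) -> GenusGroups:
    """Keep genera with at least ``min_deep`` deep and ``min_shallow`` shallow
    species, counting before any equalization."""
    return {
        g: (d, s)
        for g, (d, s) in groups.items()
        if len(d) >= min_deep and len(s) >= min_shallow
    }


def build_genus_pairs(
    groups: GenusGroups | Mapping[str, tuple[Sequence[SpeciesRecord], Sequence[SpeciesRecord]]],
    scheme: PairingScheme = "all_means",
) -> list[GenusPair]:
    """One GenusPair per genus under the requested balancing scheme."""
    pairs: list[GenusPair] = []
    for genus, (deep, shallow) in groups.items():
        if scheme == "all_means":
            d_sel, s_sel = list(deep), list(shallow)
        elif scheme == "equalized":
            d_sel, s_sel = equalize_counts(deep, shallow)
        elif scheme == "single_pair":
            d_one, s_one = select_single_pair(deep, shallow)
            d_sel, s_sel = [d_one], [s_one]
        else:
            raise ValueError(f"unknown pairing scheme {scheme!r}")
        pairs.append(pair_all_means(d_sel, s_sel, genus=genus, scheme=scheme))
    return pairs
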