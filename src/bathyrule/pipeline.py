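"""End-to-end analysis runs: classify, pair, regress, permute, report.

`run_analysis` executes one full configuration (a depth rule, optional
abyssal/bathypelagic exclusion, a pairing scheme, minimum-count filter,
both regressions and the permutation test) and returns a flat,
JSON-serializable record with provenance.  `run_table_suite` maps the
named result-table layouts onto collections of such runs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np

from bathyrule._version import __version__ as _version
from bathyrule.depth import (
    DepthRule,
    ExclusionMode,
    classify_table,
    exclude_by_depth,
    records_excluded_by_depth,
)
from bathyrule.errors import DegenerateDataError
from bathyrule.pairing import (
    PairingScheme,
    build_genus_pairs,
    filter_min_counts,
    group_into_genera,
)
from bathyrule.permutation import (
    RelabelScheme,
    Tail,
    ols_randomization_study,
    permutation_test,
)
from bathyrule.regression import common_slope_test, ols_fit, sma_fit
from bathyrule.tables import SpeciesTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisSpec:
    """One complete analysis configuration."""

    rule: DepthRule = field(default_factory=DepthRule)
    exclusion: tuple[ExclusionMode, float] | None = None
    pairing: PairingScheme = "all_means"
    min_deep: int = 1
    min_shallow: int = 1
    n_permutations: int = 100_000
    tail: Tail = "directional_doubled"
    seed: int | None = None
    run_randomization: bool = False
    n_randomizations: int = 100_000
    randomization_scheme: RelabelScheme = "group_swap"
    clade_map: dict[str, str] | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.exclusion is not None:
            mode, threshold = self.exclusion
            if threshold <= (self.rule.deep_cutoff_m or 0):
                raise ValueError("exclusion threshold must exceed the deep cutoff")
        if self.min_deep < 1 or self.min_shallow < 1:
            raise ValueError("minimum counts must be >= 1")


def _table_checksum(table: SpeciesTable) -> str:
    h = hashlib.md5()
    for r in table:
        h.update(
            f"{r.taxon_name}\t{r.genus}\t{r.shell_length_mm!r}\t"
            f"{r.depth_min_m!r}\t{r.depth_max_m!r}\n".encode()
        )
    return h.hexdigest()


def read_clade_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (genus, clade label); '#' comments ignored."""
    mapping: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"clade map line lacks two columns: {line!r}")
        mapping[parts[0]] = parts[1]
    return mapping


def run_analysis(table: SpeciesTable, spec: AnalysisSpec) -> dict[str, Any]:
    """Run one configuration end to end; deterministic given ``spec.seed``."""
    checksum = _table_checksum(table)
    record: dict[str, Any] = {"label": spec.label}

    # Exclusion accounting (both counters: all species, and species that
    # would otherwise have entered the analysis).
    s_excluded_total = 0
    s_excluded_classified = 0
    working = table
    if spec.exclusion is not None:
        mode, threshold = spec.exclusion
        pre_assignments = classify_table(table, spec.rule)
        pre_groups = filter_min_counts(
            group_into_genera(table, pre_assignments), spec.min_deep, spec.min_shallow
        )
        analysed = [r for d, s in pre_groups.values() for r in (*d, *s)]
        s_excluded_classified = len(records_excluded_by_depth(analysed, mode, threshold))
        working, s_excluded_total = exclude_by_depth(table, mode, threshold)

    assignments = classify_table(working, spec.rule)
    n_deep = sum(a.category == "deep" for a in assignments)
    n_shallow = sum(a.category == "shallow" for a in assignments)
    groups = group_into_genera(working, assignments)
    n_two_sided = len(groups)
    groups = filter_min_counts(groups, spec.min_deep, spec.min_shallow)
    pairs = build_genus_pairs(groups, spec.pairing)
    logger.info(
        "%s: %d deep / %d shallow species; %d two-sided genera, %d after min-count filter",
        spec.label or "analysis",
        n_deep,
        n_shallow,
        n_two_sided,
        len(groups),
    )

    record.update(
        n_genera=len(groups),
        n_genera_two_sided=n_two_sided,
        n_deep_species=n_deep,
        n_shallow_species=n_shallow,
        s_excluded=s_excluded_classified,
        s_excluded_total=s_excluded_total,
    )

    try:
        ols = ols_fit(pairs)
        sma = sma_fit(pairs)
        perm = permutation_test(
            groups,
            pairing=spec.pairing,
            n_permutations=spec.n_permutations,
            seed=spec.seed,
            tail=spec.tail,
        )
    except DegenerateDataError as exc:
        raise DegenerateDataError(f"regression stage ({spec.label or 'analysis'}): {exc}") from exc
    record.update(
        b_ols=ols.slope,
        t_ols=ols.statistic,
        p_ols=ols.p_value,
        b_sma=sma.slope,
        sma_statistic=sma.statistic,
        p_perm=perm.p_two_tailed,
        n_permutations=perm.n_permutations,
    )

    if spec.run_randomization:
        rand = ols_randomization_study(
            groups,
            pairing=spec.pairing,
            n_randomizations=spec.n_randomizations,
            seed=spec.seed,
            scheme=spec.randomization_scheme,
        )
        record.update(
            fraction_stronger=rand.fraction_stronger,
            randomization_scheme=rand.scheme,
            n_randomizations=rand.n_randomizations,
        )

    if spec.clade_map is not None:
        grouped: dict[str, list] = {}
        for genus, (d, s) in groups.items():
            clade = spec.clade_map.get(genus)
            if clade is None:
                continue
            grouped.setdefault(clade, []).append((genus, (d, s)))
        usable = {
            clade: build_genus_pairs(dict(members), spec.pairing)
            for clade, members in grouped.items()
            if len(members) >= 3
        }
        if len(usable) >= 2:
            cs = common_slope_test(usable)
            record.update(
                common_slope=cs.common_slope,
                common_slope_lr=cs.lr_statistic,
                common_slope_p=cs.p_value,
                clades=list(cs.groups),
            )
        else:
            logger.warning("clade comparison skipped: fewer than two usable clades")

    record["provenance"] = {
        "package_version": _version,
        "input_checksum_md5": checksum,
        "input_source": table.source,
        "seed": spec.seed,
        "rule": {
            "scheme": spec.rule.scheme,
            "boundary_m": spec.rule.boundary_m,
            "deep_cutoff_m": spec.rule.deep_cutoff_m,
        },
        "exclusion": list(spec.exclusion) if spec.exclusion else None,
        "pairing": spec.pairing,
        "min_deep": spec.min_deep,
        "min_shallow": spec.min_shallow,
        "tail": spec.tail,
    }
    return record


_CUTOFFS = (200.0, 400.0, 600.0, 800.0)
_SCHEMES: tuple[PairingScheme, ...] = ("all_means", "equalized", "single_pair")


def _suite_specs(suite: str, seed: int | None, n_permutations: int) -> list[AnalysisSpec]:
    rng = np.random.default_rng(seed)

    def next_seed() -> int | None:
        return None if seed is None else int(rng.integers(2**31))

    specs: list[AnalysisSpec] = []
    if suite in ("table1A", "table1B"):
        min_count = 1 if suite == "table1A" else 2
        for cutoff in _CUTOFFS:
            for scheme in _SCHEMES:
                specs.append(
                    AnalysisSpec(
                        rule=DepthRule(scheme="strict", boundary_m=200.0, deep_cutoff_m=cutoff),
                        pairing=scheme,
                        min_deep=min_count,
                        min_shallow=min_count,
                        n_permutations=n_permutations,
                        seed=next_seed(),
                        label=f"{suite}:>{cutoff:.0f}m:{scheme}",
                    )
                )
    elif suite == "table2":
        exclusions: list[tuple[ExclusionMode, float]] = [
            ("range_min_exceeds", 3000.0),
            ("range_max_exceeds", 3000.0),
            ("range_min_exceeds", 1000.0),
            ("range_max_exceeds", 1000.0),
        ]
        parts = (("A", 400.0, 1), ("B", 200.0, 2))
        for mode, threshold in exclusions:
            for part, cutoff, min_count in parts:
                specs.append(
                    AnalysisSpec(
                        rule=DepthRule(scheme="strict", boundary_m=200.0, deep_cutoff_m=cutoff),
                        exclusion=(mode, threshold),
                        pairing="all_means",
                        min_deep=min_count,
                        min_shallow=min_count,
                        n_permutations=n_permutations,
                        seed=next_seed(),
                        label=f"table2:{part}:{mode}>{threshold:.0f}m",
                    )
                )
    elif suite == "fig1A":
        specs.append(
            AnalysisSpec(
                rule=DepthRule(scheme="midpoint", boundary_m=200.0),
                pairing="all_means",
                n_permutations=n_permutations,
                seed=next_seed(),
                run_randomization=True,
                n_randomizations=n_permutations,
                label="fig1A:midpoint:all_means",
            )
        )
    else:
        raise ValueError(f"unknown suite {suite!r}")
    return specs


def run_table_suite(
    table: SpeciesTable,
    suite: str,
    seed: int | None = None,
    n_permutations: int = 100_000,
) -> list[dict[str, Any]]:
    """Run every cell-group of a named result table.

    Suites: ``table1A`` (4 strict cutoffs x 3 pairing schemes),
    ``table1B`` (same, with the >=2 deep / >=2 shallow genus filter),
    ``table2`` (4 depth-exclusion settings x 2 parts), ``fig1A`` (midpoint
    rule, all-means pairing, with the OLS randomization study).
    """
    results = []
    for spec in _suite_specs(suite, seed, n_permutations):
        try:
            results.append(run_analysis(table, spec))
        except DegenerateDataError as exc:
            logger.warning("%s: skipped (%s)", spec.label, exc)
            results.append({"label": spec.label, "error": str(exc)})
    return results


def results_to_tsv(results: Sequence[dict[str, Any]]) -> str:
    """Flatten suite results to a TSV report (p-values to 3 decimals)."""
    cols = ["label", "n_genera", "b_sma", "p_perm", "b_ols", "p_ols", "s_excluded"]
    lines = ["\t".join(cols)]
    for rec in results:
        row = []
        for c in cols:
            v = rec.get(c)
            if v is None:
                row.append("NA")
            elif c.startswith("p_"):
                row.append(f"{v:.3f}")
            elif isinstance(v, float):
                row.append(f"{v:.4f}")
            else:
                row.append(str(v))
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
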