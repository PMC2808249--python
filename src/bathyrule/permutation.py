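"""Within-genus label permutation inference and the OLS randomization study.

Genus membership is fixed biology, but under the null hypothesis that
deep-sea colonization leaves body-size evolution unchanged, the deep /
shallow labels within a genus are exchangeable.  The permutation null is
therefore built by uniformly re-partitioning each genus's species into new
deep and shallow sets of the original sizes, re-running the *entire*
pairing scheme (means re-averaged; equalization and single-pair selection
re-applied, since the selection is part of the statistic), and recomputing
the SMA statistic r(x+y, x−y).  The p-value is the proportion of
permuted statistics at least as extreme as the observed one, in the
observed direction, doubled for a two-tailed test and capped at one; the
observed statistic is not added to numerator or denominator.

The OLS randomization study applies the same relabeling idea to the
classical test: it measures how often *random* deep/shallow assignments
produce apparent island-rule support (a one-sided t statistic for slope <
1) at least as strong as the real data's — a direct demonstration that a
small OLS p-value can be unremarkable.

All replicate generation is vectorized per genus and chunked; per-genus
random streams are derived from the seed by `numpy` seed-sequence spawning,
so results are reproducible bit-for-bit and independent of chunk size.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterator, Literal, Sequence

import numpy as np

from bathyrule.errors import DegenerateDataError
from bathyrule.pairing import (
    GenusGroups,
    PairingScheme,
    build_genus_pairs,
    sort_for_selection,
)
from bathyrule.regression import ols_fit, sma_fit
from bathyrule.tables import SpeciesRecord

Tail = Literal["directional_doubled", "absolute"]
RelabelScheme = Literal["species_relabel", "group_swap"]

_CHUNK = 10_000


@dataclass(frozen=True)
class PermutationResult:
    observed_statistic: float
    n_permutations: int
    p_two_tailed: float
    seed: int | None
    scheme: RelabelScheme
    pairing: PairingScheme
    tail: Tail
    n_degenerate: int = 0
    exhaustive: bool = False


@dataclass(frozen=True)
class RandomizationStudyResult:
    n_randomizations: int
    fraction_stronger: float
    reference_statistic: float
    seed: int | None
    scheme: RelabelScheme
    pairing: PairingScheme
    n_degenerate: int = 0


def permute_within_genus(
    deep: Sequence[SpeciesRecord],
    shallow: Sequence[SpeciesRecord],
    rng: np.random.Generator,
) -> tuple[list[SpeciesRecord], list[SpeciesRecord]]:
    """Uniformly re-partition one genus's species into same-size sets."""
    pool = list(deep) + list(shallow)
    order = rng.permutation(len(pool))
    n_deep = len(deep)
    new_deep = [pool[i] for i in order[:n_deep]]
    new_shallow = [pool[i] for i in order[n_deep:]]
    return new_deep, new_shallow


class _GenusArrays:
    """Per-genus numeric arrays in canonical tie-break order.

    Canonical order is (shell length, taxon name) ascending, so stable
    sorts on midpoints reproduce the deterministic tie-breaking of the
    scalar pairing functions.
    """

    __slots__ = ("genus", "logsize", "midpoint", "n_deep", "n_shallow")

    def __init__(self, genus: str, deep: Sequence[SpeciesRecord], shallow: Sequence[SpeciesRecord]):
        pool = sort_for_selection(list(deep) + list(shallow))
        self.genus = genus
        self.logsize = np.array([r.log_size for r in pool], dtype=float)
        self.midpoint = np.array([r.depth_midpoint_m for r in pool], dtype=float)
        self.n_deep = len(deep)
        self.n_shallow = len(shallow)

    @property
    def n(self) -> int:
        return self.n_deep + self.n_shallow

    def pair_xy(self, deep_idx: np.ndarray, shallow_idx: np.ndarray, scheme: PairingScheme):
        """(x, y) per replicate row for given per-row index matrices.

        Rows of ``deep_idx``/``shallow_idx`` must be sorted ascending so
        that within-row order is canonical.
        """
        logs, mids = self.logsize, self.midpoint
        d, s = deep_idx.shape[1], shallow_idx.shape[1]
        k = min(d, s)
        if scheme == "all_means":
            return logs[shallow_idx].mean(axis=1), logs[deep_idx].mean(axis=1)
        if scheme == "equalized":
            if d <= s:
                y = logs[deep_idx].mean(axis=1)
                sel = np.argsort(mids[shallow_idx], axis=1, kind="stable")[:, :k]
                x = np.take_along_axis(logs[shallow_idx], sel, axis=1).mean(axis=1)
            else:
                x = logs[shallow_idx].mean(axis=1)
                sel = np.argsort(-mids[deep_idx], axis=1, kind="stable")[:, :k]
                y = np.take_along_axis(logs[deep_idx], sel, axis=1).mean(axis=1)
            return x, y
        if scheme == "single_pair":
            rows = np.arange(deep_idx.shape[0])
            di = np.argmax(mids[deep_idx], axis=1)
            si = np.argmin(mids[shallow_idx], axis=1)
            return logs[shallow_idx][rows, si], logs[deep_idx][rows, di]
        raise ValueError(f"unknown pairing scheme {scheme!r}")

    def random_xy(self, m: int, rng: np.random.Generator, scheme: PairingScheme):
        """(x, y) for ``m`` uniform random relabelings of this genus."""
        order = rng.random((m, self.n)).argsort(axis=1)
        deep_idx = np.sort(order[:, : self.n_deep], axis=1)
        shallow_idx = np.sort(order[:, self.n_deep :], axis=1)
        return self.pair_xy(deep_idx, shallow_idx, scheme)


def _prepare(genera: GenusGroups) -> list[_GenusArrays]:
    if len(genera) < 3:
        raise DegenerateDataError(f"need at least 3 genera, got {len(genera)}")
    return [_GenusArrays(g, d, s) for g, (d, s) in genera.items()]


def _observed_xy(genera: GenusGroups, scheme: PairingScheme) -> tuple[np.ndarray, np.ndarray]:
    pairs = build_genus_pairs(genera, scheme)
    x = np.array([p.x_shallow_logsize for p in pairs])
    y = np.array([p.y_deep_logsize for p in pairs])
    return x, y


def _row_sma_statistic(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """r(x+y, x−y) per replicate row; second value flags degenerate rows."""
    S, D = X + Y, X - Y
    Sc = S - S.mean(axis=1, keepdims=True)
    Dc = D - D.mean(axis=1, keepdims=True)
    den2 = (Sc**2).sum(axis=1) * (Dc**2).sum(axis=1)
    # ptp catches exactly-constant rows that mean-subtraction rounding misses
    degenerate = (den2 <= 0.0) | (np.ptp(S, axis=1) == 0) | (np.ptp(D, axis=1) == 0)
    stat = np.zeros(X.shape[0])
    ok = ~degenerate
    stat[ok] = (Sc[ok] * Dc[ok]).sum(axis=1) / np.sqrt(den2[ok])
    return stat, degenerate


def _row_ols_t(X: np.ndarray, Y: np.ndarray, null_slope: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """t = (b − 1)/SE(b) per replicate row for OLS of y on x."""
    n = X.shape[1]
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sxx = (Xc**2).sum(axis=1)
    sxy = (Xc * Yc).sum(axis=1)
    syy = (Yc**2).sum(axis=1)
    degenerate = (sxx <= 0.0) | (np.ptp(X, axis=1) == 0)
    t = np.zeros(X.shape[0])
    ok = ~degenerate
    b = sxy[ok] / sxx[ok]
    sse = np.maximum(syy[ok] - b * sxy[ok], 0.0)
    se2 = sse / (n - 2) / sxx[ok]
    zero_se = se2 <= 0.0
    degenerate[np.flatnonzero(ok)[zero_se]] = True
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = (b - null_slope) / np.sqrt(se2)
    tvals[zero_se] = 0.0
    t[ok] = tvals
    return t, degenerate


def _replicate_statistics(
    arrays: list[_GenusArrays],
    n_replicates: int,
    seed: int | None,
    scheme: PairingScheme,
    stat: Literal["sma", "ols_t"],
) -> tuple[np.ndarray, int]:
    """Replicate statistics under within-genus relabeling, chunked."""
    children = np.random.SeedSequence(seed).spawn(len(arrays))
    rngs = [np.random.default_rng(c) for c in children]
    out = np.empty(n_replicates)
    n_degenerate = 0
    G = len(arrays)
    done = 0
    while done < n_replicates:
        m = min(_CHUNK, n_replicates - done)
        X = np.empty((m, G))
        Y = np.empty((m, G))
        for j, (ga, rng) in enumerate(zip(arrays, rngs)):
            X[:, j], Y[:, j] = ga.random_xy(m, rng, scheme)
        if stat == "sma":
            vals, degenerate = _row_sma_statistic(X, Y)
        else:
            vals, degenerate = _row_ols_t(X, Y)
        # degenerate replicates count as non-exceeding: push to the null center
        vals[degenerate] = 0.0
        n_degenerate += int(degenerate.sum())
        out[done : done + m] = vals
        done += m
    if n_degenerate == n_replicates:
        raise DegenerateDataError("all permutation replicates were degenerate")
    return out, n_degenerate


def _one_sided_count(values: np.ndarray, observed: float) -> int:
    if observed >= 0:
        return int(np.count_nonzero(values >= observed))
    return int(np.count_nonzero(values <= observed))


def _group_swap_statistics(
    genera: GenusGroups,
    pairing: PairingScheme,
    n_replicates: int,
    seed: int | None,
    stat: Literal["sma", "ols_t"],
) -> tuple[np.ndarray, int]:
    """Replicate statistics when whole deep/shallow sets swap per genus.

    Pairing is re-run with the roles exchanged, so equalization and
    single-pair selection see the swapped groups.
    """
    x_obs, y_obs = _observed_xy(genera, pairing)
    swapped = {g: (s, d) for g, (d, s) in genera.items()}
    x_swp, y_swp = _observed_xy(swapped, pairing)
    rng = np.random.default_rng(seed)
    G = x_obs.size
    out = np.empty(n_replicates)
    n_degenerate = 0
    done = 0
    while done < n_replicates:
        m = min(_CHUNK, n_replicates - done)
        flip = rng.random((m, G)) < 0.5
        X = np.where(flip, x_swp, x_obs)
        Y = np.where(flip, y_swp, y_obs)
        vals, degenerate = _row_sma_statistic(X, Y) if stat == "sma" else _row_ols_t(X, Y)
        vals[degenerate] = 0.0
        n_degenerate += int(degenerate.sum())
        out[done : done + m] = vals
        done += m
    if n_degenerate == n_replicates:
        raise DegenerateDataError("all replicates were degenerate")
    return out, n_degenerate


def _exhaustive_xy(
    arrays: list[_GenusArrays], scheme: PairingScheme, limit: int
) -> tuple[np.ndarray, np.ndarray]:
    """(x, y) for every distinct within-genus relabeling (size-preserving)."""
    counts = [math.comb(ga.n, ga.n_deep) for ga in arrays]
    total = math.prod(counts)
    if total > limit:
        raise ValueError(f"{total} relabelings exceed exhaustive limit {limit}")
    per_genus: list[tuple[np.ndarray, np.ndarray]] = []
    for ga in arrays:
        all_idx = set(range(ga.n))
        deep_rows = []
        shallow_rows = []
        for combo in itertools.combinations(range(ga.n), ga.n_deep):
            deep_rows.append(combo)
            shallow_rows.append(sorted(all_idx - set(combo)))
        xg, yg = ga.pair_xy(np.array(deep_rows), np.array(shallow_rows), scheme)
        per_genus.append((xg, yg))
    grids = np.meshgrid(*[np.arange(c) for c in counts], indexing="ij")
    X = np.column_stack(
        [per_genus[j][0][g.ravel()] for j, g in enumerate(grids)]
    )
    Y = np.column_stack(
        [per_genus[j][1][g.ravel()] for j, g in enumerate(grids)]
    )
    return X, Y


def permutation_test(
    genera: GenusGroups,
    pairing: PairingScheme = "all_means",
    n_permutations: int = 100_000,
    seed: int | None = None,
    tail: Tail = "directional_doubled",
    scheme: RelabelScheme = "species_relabel",
    exhaustive: bool = False,
    exhaustive_limit: int = 200_000,
) -> PermutationResult:
    """Two-tailed permutation test of the SMA statistic r(x+y, x−y).

    ``scheme`` selects the relabeling null: ``species_relabel`` (the
    default) re-partitions species within each genus; ``group_swap``
    exchanges each genus's whole deep and shallow sets with probability
    1/2.  With ``exhaustive=True`` every distinct species relabeling is
    enumerated instead of sampled (small problems only) and ``seed`` is
    ignored.
    """
    if not exhaustive and n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    arrays = _prepare(genera)
    x_obs, y_obs = _observed_xy(genera, pairing)
    observed = sma_fit((x_obs, y_obs)).statistic

    if exhaustive:
        if scheme != "species_relabel":
            raise ValueError("exhaustive enumeration supports species_relabel only")
        X, Y = _exhaustive_xy(arrays, pairing, exhaustive_limit)
        values, degenerate = _row_sma_statistic(X, Y)
        values[degenerate] = 0.0
        n_reps = values.size
        n_degenerate = int(degenerate.sum())
    elif scheme == "group_swap":
        values, n_degenerate = _group_swap_statistics(
            genera, pairing, n_permutations, seed, "sma"
        )
        n_reps = n_permutations
    else:
        values, n_degenerate = _replicate_statistics(
            arrays, n_permutations, seed, pairing, "sma"
        )
        n_reps = n_permutations

    if tail == "directional_doubled":
        p = min(1.0, 2.0 * _one_sided_count(values, observed) / n_reps)
    elif tail == "absolute":
        p = np.count_nonzero(np.abs(values) >= abs(observed)) / n_reps
    else:
        raise ValueError(f"unknown tail {tail!r}")
    p = max(p, 1.0 / n_reps)  # a permutation p of exactly 0 is not reportable
    return PermutationResult(
        observed_statistic=observed,
        n_permutations=n_reps,
        p_two_tailed=float(p),
        seed=seed,
        scheme=scheme,
        pairing=pairing,
        tail=tail,
        n_degenerate=n_degenerate,
        exhaustive=exhaustive,
    )


def ols_randomization_study(
    genera: GenusGroups,
    pairing: PairingScheme = "all_means",
    n_randomizations: int = 100_000,
    seed: int | None = None,
    scheme: RelabelScheme = "group_swap",
) -> RandomizationStudyResult:
    """How often random deep/shallow labels beat the real OLS support.

    The support statistic is the one-sided t for slope < 1 (more negative =
    stronger apparent island-rule signal).  ``group_swap`` exchanges each
    genus's whole deep and shallow sets with probability 1/2;
    ``species_relabel`` re-partitions species within each genus as in
    :func:`permutation_test`.  Returns the fraction of randomized data sets
    whose support is at least as strong as the real data's.
    """
    if n_randomizations < 1:
        raise ValueError("n_randomizations must be >= 1")
    arrays = _prepare(genera)
    x_obs, y_obs = _observed_xy(genera, pairing)
    t_obs = ols_fit((x_obs, y_obs)).statistic

    if scheme == "species_relabel":
        values, n_degenerate = _replicate_statistics(
            arrays, n_randomizations, seed, pairing, "ols_t"
        )
    elif scheme == "group_swap":
        values, n_degenerate = _group_swap_statistics(
            genera, pairing, n_randomizations, seed, "ols_t"
        )
    else:
        raise ValueError(f"unknown relabeling scheme {scheme!r}")

    fraction = float(np.count_nonzero(values <= t_obs) / n_randomizations)
    return RandomizationStudyResult(
        n_randomizations=n_randomizations,
        fraction_stronger=fraction,
        reference_statistic=float(t_obs),
        seed=seed,
        scheme=scheme,
        pairing=pairing,
        n_degenerate=n_degenerate,
    )
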