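"""Within-genus relabeling machinery and permutation inference."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from bathyrule.depth import DepthRule, classify_table
from bathyrule.errors import DegenerateDataError
from bathyrule.pairing import group_into_genera
from bathyrule.permutation import (
    ols_randomization_study,
    permutation_test,
    permute_within_genus,
)
from bathyrule.regression import sma_statistic
from bathyrule.simulate import SimulationConfig, simulate_null_with_mainland_drift

from conftest import groups_from, random_genus, rec


class TestPermuteWithinGenus:
    def test_sizes_are_preserved(self, rng):
        deep, shallow = random_genus(rng, 2, 5)
        for _ in range(20):
            d2, s2 = permute_within_genus(deep, shallow, rng)
            assert len(d2) == 2 and len(s2) == 5
            assert sorted(r.taxon_name for r in d2 + s2) == sorted(
                r.taxon_name for r in deep + shallow
            )

    def test_one_one_genus_swaps_half_the_time(self, rng):
        deep, shallow = random_genus(rng, 1, 1)
        swaps = sum(
            permute_within_genus(deep, shallow, rng)[0][0].taxon_name
            != deep[0].taxon_name
            for _ in range(4000)
        )
        assert stats.binomtest(swaps, 4000, 0.5).pvalue > 1e-3

    def test_partitions_are_uniform_over_all_ten(self, rng):
        """2 deep + 3 shallow: C(5,2)=10 equally likely deep sets."""
        deep, shallow = random_genus(rng, 2, 3)
        counts: dict[frozenset, int] = {}
        n_draws = 30_000
        for _ in range(n_draws):
            d2, _ = permute_within_genus(deep, shallow, rng)
            counts[frozenset(r.taxon_name for r in d2)] = (
                counts.get(frozenset(r.taxon_name for r in d2), 0) + 1
            )
        assert len(counts) == 10
        chi2 = stats.chisquare(list(counts.values()))
        assert chi2.pvalue > 1e-4


def _tiny_groups(rng, spec=((1, 2), (1, 2), (1, 1))):
    return groups_from(
        *(random_genus(rng, d, s, f"T{i}") for i, (d, s) in enumerate(spec))
    )


def _enumerate_statistics(groups):
    """Independent oracle: enumerate every relabeling with plain numpy."""
    per_genus = []
    for deep, shallow in groups.values():
        pool = deep + shallow
        logs = np.log10([r.shell_length_mm for r in pool])
        nd = len(deep)
        options = []
        for combo in itertools.combinations(range(len(pool)), nd):
            mask = np.zeros(len(pool), dtype=bool)
            mask[list(combo)] = True
            options.append((logs[~mask].mean(), logs[mask].mean()))
        per_genus.append(options)
    stats_all = []
    for choice in itertools.product(*per_genus):
        x = np.array([c[0] for c in choice])
        y = np.array([c[1] for c in choice])
        stats_all.append(sma_statistic(x, y))
    return np.array(stats_all)


class TestPermutationTest:
    def test_same_seed_reproduces_p_exactly(self, rng):
        groups = groups_from(*(random_genus(rng, 2, 3, f"G{i}") for i in range(6)))
        a = permutation_test(groups, n_permutations=2000, seed=42)
        b = permutation_test(groups, n_permutations=2000, seed=42)
        assert a.p_two_tailed == b.p_two_tailed
        assert a.observed_statistic == b.observed_statistic

    def test_exhaustive_matches_independent_enumeration(self, rng):
        groups = _tiny_groups(rng)
        res = permutation_test(groups, exhaustive=True)
        all_stats = _enumerate_statistics(groups)
        assert res.n_permutations == all_stats.size
        observed = res.observed_statistic
        if observed >= 0:
            count = np.count_nonzero(all_stats >= observed)
        else:
            count = np.count_nonzero(all_stats <= observed)
        expected = min(1.0, 2.0 * count / all_stats.size)
        assert res.p_two_tailed == pytest.approx(expected)

    def test_monte_carlo_converges_to_exhaustive(self, rng):
        groups = _tiny_groups(rng, spec=((1, 2), (1, 1), (1, 1)))  # 3*2*2=12 relabelings
        exact = permutation_test(groups, exhaustive=True)
        n = 100_000
        mc = permutation_test(groups, n_permutations=n, seed=7)
        p1 = exact.p_two_tailed / 2  # one-sided exceedance probabilities
        se = math.sqrt(p1 * (1 - p1) / n)
        assert abs(mc.p_two_tailed - exact.p_two_tailed) <= 2 * 3 * se

    def test_absolute_tail_option(self, rng):
        groups = groups_from(*(random_genus(rng, 1, 2, f"G{i}") for i in range(5)))
        res = permutation_test(groups, n_permutations=500, seed=3, tail="absolute")
        assert 0 < res.p_two_tailed <= 1
        assert res.tail == "absolute"

    def test_all_degenerate_raises(self):
        groups = groups_from(
            *(
                (
                    [rec(f"d{i}", f"Z{i}", 10.0, 500, 900)],
                    [rec(f"s{i}", f"Z{i}", 10.0, 5, 50)],
                )
                for i in range(3)
            )
        )
        with pytest.raises(DegenerateDataError):
            permutation_test(groups, n_permutations=50, seed=1)

    def test_group_swap_scheme_is_exact_under_lineage_drift(self):
        """Whole-group swapping preserves the joint law when the two lineage
        drifts are identically distributed, so its rejection rate is nominal
        even though species within a lineage are correlated."""
        rng = np.random.default_rng(501)
        rule = DepthRule(scheme="strict", deep_cutoff_m=400)
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            cfg = SimulationConfig(
                n_genera=60,
                beta_effect=1.0,
                sigma_shallow_drift=0.3,
                sigma_deep_drift=0.3,
                sigma_within=0.1,
                seed=int(rng.integers(2**31)),
            )
            table = simulate_null_with_mainland_drift(cfg)
            groups = group_into_genera(table, classify_table(table, rule))
            res = permutation_test(
                groups,
                n_permutations=400,
                seed=int(rng.integers(2**31)),
                scheme="group_swap",
            )
            rejections += res.p_two_tailed <= 0.05
        rate = rejections / n_rep
        half_width = 1.96 * math.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) <= half_width


class TestRandomizationStudy:
    def test_strong_true_effect_is_rarely_beaten(self):
        # noise-free convergence (beta = 0.3): random relabelings should
        # essentially never show stronger apparent support than the data
        rng = np.random.default_rng(11)
        groups = {}
        for i in range(40):
            mu = rng.normal(1.2, 0.5)
            deep = [rec(f"G{i} d", f"G{i}", float(10 ** (1.2 + 0.3 * (mu - 1.2))), 500, 900)]
            shallow = [rec(f"G{i} s", f"G{i}", float(10**mu), 5, 50)]
            groups[f"G{i}"] = (deep, shallow)
        res = ols_randomization_study(groups, n_randomizations=2000, seed=5)
        assert res.fraction_stronger < 0.05

    def test_seed_determinism_and_schemes(self, rng):
        groups = groups_from(*(random_genus(rng, 2, 4, f"G{i}") for i in range(8)))
        for scheme in ("group_swap", "species_relabel"):
            a = ols_randomization_study(groups, n_randomizations=1000, seed=9, scheme=scheme)
            b = ols_randomization_study(groups, n_randomizations=1000, seed=9, scheme=scheme)
            assert a.fraction_stronger == b.fraction_stronger
            assert 0.0 <= a.fraction_stronger <= 1.0

    def test_null_data_fraction_is_large(self):
        """Under a label-exchangeable null about half of random relabelings
        should look at least as island-rule-like as the data."""
        rng = np.random.default_rng(23)
        groups = groups_from(*(random_genus(rng, 2, 3, f"G{i}") for i in range(50)))
        res = ols_randomization_study(groups, n_randomizations=4000, seed=13)
        assert 0.1 < res.fraction_stronger < 0.9
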