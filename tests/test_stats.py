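"""Statistical kernel tests against brute-force and closed-form oracles."""

import math
from itertools import combinations, permutations

import numpy as np
import pytest
import scipy.stats as sps

from chromarm import stats
from conftest import oracle_exact_p_bounds, random_contingency_table


class TestFisherExact2x2:
    def test_symmetric_table_is_null(self):
        assert stats.fisher_exact_2x2([[3, 3], [3, 3]]).p == pytest.approx(1.0)

    def test_printed_sex_table_highly_significant(self):
        # female/male split by arm status in a large HPV-negative cohort
        assert stats.fisher_exact_2x2([[69, 40], [224, 42]]).p <= 1e-4

    def test_perfect_separation_matches_enumeration(self):
        lo, hi = oracle_exact_p_bounds([[0, 5], [5, 0]])
        p = stats.fisher_exact_2x2([[0, 5], [5, 0]]).p
        assert float(lo) - 1e-12 <= p <= float(hi) + 1e-12

    def test_zero_margin_untestable(self):
        with pytest.warns(UserWarning):
            res = stats.fisher_exact_2x2([[0, 0], [5, 7]])
        assert res.p == 1.0

    def test_conditional_odds_ratio_and_ci_bracket_effect(self):
        res = stats.fisher_exact_2x2([[20, 5], [5, 20]])
        assert res.effect > 1
        assert res.ci_low < res.effect < res.ci_high


class TestExactRxc:
    def test_agrees_with_fisher_on_2x2(self):
        for table in ([[8, 5], [14, 32]], [[3, 3], [3, 3]], [[1, 9], [9, 1]]):
            assert stats.exact_rxc(table).p == pytest.approx(
                stats.fisher_exact_2x2(table).p, abs=1e-12)

    def test_single_effective_row_is_null(self):
        assert stats.exact_rxc([[4, 6], [0, 0], [0, 0]]).p == 1.0

    @pytest.mark.parametrize("table,expected", [
        # frozen values from R fisher.test on the same tables
        ([[6, 14], [3, 12], [14, 8]], 0.01507532),
        ([[51, 29], [29, 14], [144, 28]], 0.0009084452),
    ])
    def test_three_by_two_matches_r_oracle(self, table, expected):
        assert stats.exact_rxc(table).p == pytest.approx(expected, rel=1e-6)

    def test_capacity_guard_and_monte_carlo(self):
        big = [[100, 120, 90], [130, 80, 110], [95, 140, 105]]
        with pytest.raises(ValueError, match="max_tables"):
            stats.exact_rxc(big, max_tables=1000)
        res = stats.exact_rxc(big, max_tables=1000, monte_carlo=True,
                              n_montecarlo=2000, seed=0)
        ref = stats.chi_square_test(big)
        assert res.p == pytest.approx(ref.p, abs=0.05)


class TestChiSquare:
    def test_table_at_expectation_gives_zero_statistic(self):
        res = stats.chi_square_test([[10, 20], [20, 40]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_smoking_table_rounds_to_printed_value(self):
        res = stats.chi_square_test([[6, 14], [3, 12], [14, 8]])
        assert res.df == 2
        assert round(res.p, 3) == 0.015

    def test_2x2_statistic_equals_squared_two_proportion_z(self):
        a, b, c, d = 30, 20, 15, 35
        res = stats.chi_square_test([[a, b], [c, d]])
        p1, p2 = a / (a + b), c / (c + d)
        pp = (a + c) / (a + b + c + d)
        z = (p1 - p2) / math.sqrt(pp * (1 - pp) * (1 / (a + b) + 1 / (c + d)))
        assert res.statistic == pytest.approx(z ** 2, rel=1e-10)

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError):
            stats.chi_square_test([[0, 0], [5, 7]])


class TestMannWhitney:
    def test_identical_samples_null(self):
        assert stats.mann_whitney_u([1, 2, 3], [1, 2, 3]).p == pytest.approx(1.0)

    def test_exact_p_matches_split_enumeration(self):
        # all C(6,3)=20 group splits of {1..6}; observed split is the most
        # extreme in both directions -> two-sided p = 2/20
        x, y = [1, 2, 3], [4, 5, 6]
        res = stats.mann_whitney_u(x, y)
        pooled = sorted(x + y)
        obs_u = sum(xi > yj for xi in x for yj in y)
        count = 0
        for xs in combinations(pooled, 3):
            ys = list(pooled)
            for v in xs:
                ys.remove(v)
            u = sum(a > b for a in xs for b in ys)
            if min(u, 9 - u) <= min(obs_u, 9 - obs_u):
                count += 1
        assert res.p == pytest.approx(count / 20)

    def test_all_identical_values_warn(self):
        with pytest.warns(UserWarning):
            assert stats.mann_whitney_u([2, 2], [2, 2, 2]).p == 1.0

    def test_large_sample_close_to_permutation(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 40)
        y = rng.normal(0.6, 1, 40)
        res = stats.mann_whitney_u(x, y)
        pooled = np.concatenate([x, y])
        obs = abs(sps.mannwhitneyu(x, y).statistic - 800)
        hits = 0
        n_perm = 3000
        for _ in range(n_perm):
            rng.shuffle(pooled)
            u = sps.mannwhitneyu(pooled[:40], pooled[40:]).statistic
            hits += abs(u - 800) >= obs
        p_perm = (hits + 1) / (n_perm + 1)
        assert res.p == pytest.approx(p_perm, rel=0.3, abs=0.01)


class TestSpearman:
    def test_monotone_extremes(self):
        assert stats.spearman_correlation([1, 2, 3, 5], [2, 4, 9, 11]
                                          ).effect == pytest.approx(1.0)
        assert stats.spearman_correlation([1, 2, 3, 5], [11, 9, 4, 2]
                                          ).effect == pytest.approx(-1.0)

    def test_exact_p_for_perfect_monotone_n4(self):
        # of 4! = 24 permutations exactly two achieve |rho| = 1
        res = stats.spearman_correlation([1, 2, 3, 4], [10, 20, 30, 40])
        assert res.p == pytest.approx(2 / 24)

    def test_tied_data_matches_midrank_oracle(self):
        x = [1, 2, 2, 4, 5, 7, 7, 7]
        y = [3, 3, 5, 6, 6, 8, 9, 9]
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        rho_oracle = np.corrcoef(rx, ry)[0, 1]
        assert stats.spearman_correlation(x, y).effect == pytest.approx(
            rho_oracle, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            stats.spearman_correlation([1, 1, 1], [1, 2, 3])


class TestBHAdjust:
    def test_textbook_monotone_envelope(self):
        q = stats.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_equal_values_unchanged(self):
        assert stats.bh_adjust([0.37])[0] == pytest.approx(0.37)
        assert np.allclose(stats.bh_adjust([0.2] * 5), 0.2)

    def test_matches_definitional_step_up_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            p = rng.random(rng.integers(1, 30))
            m = p.size
            order = np.argsort(p, kind="stable")
            q_sorted = p[order] * m / np.arange(1, m + 1)
            q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
            expected = np.empty(m)
            expected[order] = np.minimum(q_sorted, 1.0)
            assert np.allclose(stats.bh_adjust(p), expected)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            stats.bh_adjust([0.5, 1.2])


class TestHypergeometricORA:
    def test_full_overlap_is_uninteresting(self):
        genes = [f"g{i}" for i in range(10)]
        assert stats.hypergeometric_ora(genes, genes, genes).p == 1.0

    def test_tail_sum_oracle(self):
        # overlap of 2 from hits=10, pathway=20, universe=100
        universe = [f"g{i}" for i in range(100)]
        pathway = universe[:20]
        hits = universe[18:28]
        res = stats.hypergeometric_ora(hits, pathway, universe)
        expected = sum(math.comb(20, k) * math.comb(80, 10 - k)
                       for k in range(2, 11)) / math.comb(100, 10)
        assert res.p == pytest.approx(expected, rel=1e-10)
        assert res.extra["overlap"] == 2

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            stats.hypergeometric_ora(["a"], ["a"], [])


class TestBoxCoxRegression:
    def test_identical_group_distributions_null(self):
        y = np.tile([1.0, 2.0, 3.0, 4.0, 5.0], 2)
        g = np.repeat([0, 1], 5)
        res = stats.boxcox_regression(y, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p == pytest.approx(1.0, abs=1e-9)

    def test_planted_shift_detected_with_correct_sign(self):
        rng = np.random.default_rng(3)
        g = np.repeat([0, 1], 150)
        y = np.exp(rng.normal(1.0 + 0.5 * g, 0.5))
        res = stats.boxcox_regression(y, g)
        assert res.statistic > 0
        assert res.p < 1e-3
        assert res.effect > 1  # ratio of means on the original scale

    def test_confounded_effect_attenuates_with_covariate(self):
        rng = np.random.default_rng(4)
        n = 400
        cov = np.repeat([0, 1], n // 2)
        # group tracks the covariate 80% of the time; outcome depends only on cov
        g = np.where(rng.random(n) < 0.8, cov, 1 - cov)
        y = np.exp(rng.normal(1.0 + 1.0 * cov, 0.5))
        naive = stats.boxcox_regression(y, g)
        adjusted = stats.boxcox_regression(y, g, covariates=cov)
        assert abs(adjusted.statistic) < abs(naive.statistic)

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValueError):
            stats.boxcox_regression([2.0] * 10, np.repeat([0, 1], 5))

    def test_nonpositive_outcome_shifted_not_rejected(self):
        rng = np.random.default_rng(6)
        y = rng.normal(0, 1, 80)  # negative values present
        g = np.repeat([0, 1], 40)
        res = stats.boxcox_regression(y, g)
        assert res.extra["shift"] > 0
        assert 0 <= res.p <= 1


def test_exact_tests_match_enumeration_on_random_small_tables():
    """Spot property: implementation p within the oracle's tie bracket."""
    rng = np.random.default_rng(21)
    for _ in range(30):
        t = random_contingency_table(rng, (2, 2), int(rng.integers(4, 40)))
        lo, hi = oracle_exact_p_bounds(t)
        p = stats.fisher_exact_2x2(t).p
        assert float(lo) - 1e-9 <= p <= float(hi) + 1e-9
    for _ in range(15):
        t = random_contingency_table(rng, (2, 3), int(rng.integers(6, 30)))
        lo, hi = oracle_exact_p_bounds(t)
        p = stats.exact_rxc(t).p
        assert float(lo) - 1e-9 <= p <= float(hi) + 1e-9
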