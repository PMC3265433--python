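import numpy as np
import pytest
from scipy import stats as sps

from spinealign.group_stats import (
    DegenerateVarianceError, GroupSample, GroupStatsError, classic_anova,
    compare_groups, levene_test, tamhane_t2, welch_anova,
)

# Step-by-step hand computation on the fixture groups
#   A = {10, 12, 14, 16}, B = {11, 13, 15}, C = {20, 22, 24, 26, 28}:
# means 13, 13, 24; variances 20/3, 4, 10; classical F = 12705/544;
# Welch weights w = n/s^2 -> F_w and df2 from the weighted-means formula;
# Levene (mean-centered) W = 36/67; pairwise Welch t with
# Welch-Satterthwaite df.
HAND = {
    "classic_F": 12705.0 / 544.0,
    "welch_F": 19.788385195694584,
    "welch_df2": 5.771044658147806,
    "levene_W": 36.0 / 67.0,
    "pairs": {
        ("A", "B"): (0.0, 4.959183673469387),
        ("A", "C"): (-5.744562646538029, 6.980769230769231),
        ("B", "C"): (-6.024948132556827, 5.88235294117647),
    },
}


class TestWelchAnova:
    def test_identical_groups_give_zero(self):
        g = [GroupSample(l, np.array([1.0, 2.0, 3.0])) for l in "abc"]
        res = welch_anova(g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_two_groups_equals_squared_welch_t(self, rng):
        a = GroupSample("a", rng.normal(0, 1, 12))
        b = GroupSample("b", rng.normal(0.8, 2, 7))
        res = welch_anova([a, b])
        t = sps.ttest_ind(a.values, b.values, equal_var=False)
        assert res.statistic == pytest.approx(t.statistic ** 2, abs=1e-9)
        assert res.p_value == pytest.approx(t.pvalue, abs=1e-9)

    def test_matches_hand_computation(self, toy_stats_groups):
        res = welch_anova(toy_stats_groups)
        assert res.statistic == pytest.approx(HAND["welch_F"], abs=1e-9)
        assert res.df1 == 2
        assert res.df2 == pytest.approx(HAND["welch_df2"], abs=1e-9)

    def test_matches_pingouin(self, toy_stats_groups):
        pg = pytest.importorskip("pingouin")
        import pandas as pd
        df = pd.DataFrame([(g.label, x) for g in toy_stats_groups
                           for x in g.values], columns=["g", "x"])
        ref = pg.welch_anova(data=df, dv="x", between="g")
        res = welch_anova(toy_stats_groups)
        assert res.statistic == pytest.approx(float(ref["F"][0]), abs=1e-9)
        assert res.p_value == pytest.approx(float(ref["p_unc"][0]), abs=1e-9)

    def test_zero_variance_rejected(self):
        g = [GroupSample("a", np.array([1.0, 1.0])),
             GroupSample("b", np.array([2.0, 3.0]))]
        with pytest.raises(DegenerateVarianceError):
            welch_anova(g)

    def test_approaches_classic_for_balanced_equal_variance(self):
        # with equal group sizes and variances the Welch statistic equals
        # the classical F up to its small-sample correction factor
        # 1 + 2(k-2)/(k^2-1) * A, which tends to 1 as n grows
        rng = np.random.default_rng(7)
        base = rng.normal(0.0, 1.0, 2000)
        groups = [GroupSample(l, base + mu)
                  for l, mu in (("a", 0.0), ("b", 0.1), ("c", 0.25))]
        fw = welch_anova(groups).statistic
        f = classic_anova(groups).statistic
        assert fw == pytest.approx(f, rel=1e-3)
        # and the exact finite-n relation holds
        k, n = 3, len(base)
        a = k * (1.0 - 1.0 / k) ** 2 / (n - 1)
        den = 1.0 + 2.0 * (k - 2) / (k ** 2 - 1.0) * a
        assert fw == pytest.approx(f / den, rel=1e-9)

    def test_null_rejection_rate_is_nominal(self):
        # three groups from one normal population with unequal n and
        # variance scaling: the Welch test should reject ~5% at alpha=0.05
        rng = np.random.default_rng(1234)
        ns, sds = (10, 15, 25), (1.0, 2.0, 3.0)
        n_sims, alpha = 10_000, 0.05
        rejections = 0
        for _ in range(n_sims):
            groups = [GroupSample(str(i), rng.normal(5.0, sd, n))
                      for i, (n, sd) in enumerate(zip(ns, sds))]
            if welch_anova(groups).p_value < alpha:
                rejections += 1
        assert rejections / n_sims == pytest.approx(alpha, abs=0.01)

    def test_power_against_surface_sized_effects(self):
        # group means matching the observed surface effects (12.66, 8.9,
        # 4.10 degrees), sd 3, n 25: power at alpha = 0.001 must exceed 95%
        rng = np.random.default_rng(99)
        means = (12.66, 8.9, 4.10)
        n_sims, hits = 2_000, 0
        for _ in range(n_sims):
            groups = [GroupSample(str(i), rng.normal(mu, 3.0, 25))
                      for i, mu in enumerate(means)]
            if welch_anova(groups).p_value < 0.001:
                hits += 1
        assert hits / n_sims > 0.95


class TestClassicAnova:
    def test_identical_means_give_zero(self):
        g = [GroupSample("a", np.array([1.0, 2.0, 3.0])),
             GroupSample("b", np.array([0.0, 2.0, 4.0]))]
        assert classic_anova(g).statistic == pytest.approx(0.0, abs=1e-12)

    def test_two_groups_equals_squared_pooled_t(self, rng):
        a = GroupSample("a", rng.normal(0, 1, 9))
        b = GroupSample("b", rng.normal(1, 1, 14))
        res = classic_anova([a, b])
        t = sps.ttest_ind(a.values, b.values, equal_var=True)
        assert res.statistic == pytest.approx(t.statistic ** 2, abs=1e-9)

    def test_matches_hand_computation_and_scipy(self, toy_stats_groups):
        res = classic_anova(toy_stats_groups)
        assert res.statistic == pytest.approx(HAND["classic_F"], abs=1e-9)
        assert (res.df1, res.df2) == (2, 9)
        ref = sps.f_oneway(*[g.values for g in toy_stats_groups])
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-9)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-9)


class TestLevene:
    def test_equal_absolute_deviations_give_zero(self):
        g = [GroupSample("a", np.array([1.0, 3.0])),
             GroupSample("b", np.array([5.0, 7.0]))]
        res = levene_test(g)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_scaling_one_group_increases_statistic(self, toy_stats_groups):
        base = levene_test(toy_stats_groups).statistic
        scaled = [GroupSample("A", toy_stats_groups[0].values * 10)] + \
            list(toy_stats_groups[1:])
        assert levene_test(scaled).statistic > base

    def test_matches_hand_computation_and_scipy(self, toy_stats_groups):
        res = levene_test(toy_stats_groups, center="mean")
        assert res.statistic == pytest.approx(HAND["levene_W"], abs=1e-9)
        ref = sps.levene(*[g.values for g in toy_stats_groups], center="mean")
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-9)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_median_center_matches_scipy(self, toy_stats_groups):
        res = levene_test(toy_stats_groups, center="median")
        ref = sps.levene(*[g.values for g in toy_stats_groups],
                         center="median")
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-9)

    def test_all_zero_deviations_degenerate(self):
        g = [GroupSample("a", np.array([2.0, 2.0])),
             GroupSample("b", np.array([3.0, 3.0]))]
        with pytest.raises(DegenerateVarianceError):
            levene_test(g)


class TestTamhaneT2:
    def test_identical_groups_nothing_significant(self):
        g = [GroupSample(l, np.array([1.0, 2.0, 3.0])) for l in "abc"]
        for pair in tamhane_t2(g, alpha=0.05):
            assert pair.p_adjusted == pytest.approx(1.0)
            assert not pair.significant

    def test_single_pair_has_no_correction(self, rng):
        a = GroupSample("a", rng.normal(0, 1, 10))
        b = GroupSample("b", rng.normal(2, 2, 8))
        (pair,) = tamhane_t2([a, b], alpha=0.05)
        t = sps.ttest_ind(a.values, b.values, equal_var=False)
        assert pair.p_raw == pytest.approx(t.pvalue, abs=1e-12)
        assert pair.p_adjusted == pytest.approx(t.pvalue, abs=1e-12)

    def test_matches_hand_computation(self, toy_stats_groups):
        results = tamhane_t2(toy_stats_groups, alpha=0.05)
        assert len(results) == 3
        for r in results:
            t_hand, df_hand = HAND["pairs"][r.pair]
            assert r.t == pytest.approx(t_hand, abs=1e-9)
            assert r.df == pytest.approx(df_hand, abs=1e-9)
            p_raw = 2.0 * sps.t.sf(abs(t_hand), df_hand)
            assert r.p_adjusted == pytest.approx(
                min(1.0, 1.0 - (1.0 - p_raw) ** 3), abs=1e-12)

    def test_sidak_level_consistent_with_adjusted_p(self, toy_stats_groups):
        alpha = 0.05
        for r in tamhane_t2(toy_stats_groups, alpha=alpha):
            assert r.significant == (r.p_adjusted < alpha) or \
                r.p_adjusted == pytest.approx(alpha)


class TestCompareGroups:
    def test_report_has_all_parts(self, toy_stats_groups):
        comp = compare_groups(toy_stats_groups, alpha=0.05)
        assert comp.classic.statistic > 0
        assert comp.welch.statistic > 0
        assert len(comp.pairwise) == 3
        assert 0 <= comp.levene.p_value <= 1

    def test_single_group_rejected(self):
        with pytest.raises(GroupStatsError):
            compare_groups([GroupSample("a", np.array([1.0, 2.0]))])
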