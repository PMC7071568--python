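"""Weighted ANOVA engine: WLS equivalence, Tukey-Kramer identities, CIs,
compact letter display and Bonferroni flags."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from scipy import stats

from uvbclines.data_io import DataValidationError
from uvbclines.groupstats import (
    SignificanceThresholds,
    WeightedGroups,
    apply_bonferroni,
    compact_letter_display,
    group_confidence_interval,
    tukey_kramer,
    weighted_anova,
    weighted_group_means,
)


def _wg(y, w, g, order=("EUR", "EAS", "AFR")):
    return WeightedGroups(np.asarray(y, float), np.asarray(w, float),
                          np.asarray(g, object), group_order=order)


def _random_instance(rng, k=3, per_group=10):
    y = rng.uniform(0, 1, k * per_group)
    w = rng.integers(5, 120, k * per_group).astype(float)
    g = np.repeat(["EUR", "EAS", "AFR"][:k], per_group)
    return _wg(y, w, g)


class TestWeightedGroupMeans:
    def test_hand_computed_weighted_mean(self):
        wg = _wg([0.2, 0.8, 0.5, 0.5, 0.5], [10, 30, 1, 1, 1],
                 ["EUR", "EUR", "EAS", "EAS", "AFR"])
        means = weighted_group_means(wg)
        assert means["EUR"][0] == pytest.approx(0.65)  # (2 + 24) / 40

    def test_equal_weights_symmetry(self):
        wg = _wg([0.4, 0.6, 0.1, 0.2], [5, 5, 5, 5], ["EUR", "EUR", "EAS", "EAS"])
        assert weighted_group_means(wg)["EUR"][0] == pytest.approx(0.5)

    def test_single_set_group_is_identity(self):
        wg = _wg([0.3, 0.1, 0.2], [7, 3, 3], ["EUR", "EAS", "EAS"])
        assert weighted_group_means(wg)["EUR"][0] == pytest.approx(0.3)


class TestWeightedAnova:
    def test_identical_values_give_null_result(self):
        res = weighted_anova(_wg([0.4] * 6, [1, 2, 3, 4, 5, 6],
                                 ["EUR", "EUR", "EAS", "EAS", "AFR", "AFR"]))
        assert res.f_stat == 0.0 and res.p_value == 1.0 and res.r2 == 0.0

    def test_equivalent_to_weighted_least_squares(self, rng):
        """ANOVA decomposition == WLS on group indicators, to 1e-10."""
        for _ in range(25):
            wg = _random_instance(rng)
            res = weighted_anova(wg)
            d = np.column_stack([(wg.groups == g).astype(float)
                                 for g in wg.group_order[1:]])
            fit = sm.WLS(wg.y, sm.add_constant(d), weights=wg.w).fit()
            assert res.f_stat == pytest.approx(fit.fvalue, abs=1e-10, rel=1e-10)
            assert res.p_value == pytest.approx(fit.f_pvalue, abs=1e-10)
            assert res.r2 == pytest.approx(fit.rsquared, abs=1e-10)
            assert res.adj_r2 == pytest.approx(fit.rsquared_adj, abs=1e-10)

    def test_two_group_f_equals_squared_pooled_t(self, rng):
        y = rng.uniform(0, 1, 16)
        wg = _wg(y, np.ones(16), ["EUR"] * 8 + ["EAS"] * 8, order=("EUR", "EAS"))
        res = weighted_anova(wg)
        t, p = stats.ttest_ind(y[:8], y[8:])
        assert res.f_stat == pytest.approx(t**2)
        assert res.p_value == pytest.approx(p)

    def test_permutation_and_weight_scale_invariance(self, rng):
        wg = _random_instance(rng)
        res = weighted_anova(wg)
        perm = rng.permutation(wg.y.size)
        res_perm = weighted_anova(_wg(wg.y[perm], wg.w[perm], wg.groups[perm]))
        res_scaled = weighted_anova(_wg(wg.y, 7.5 * wg.w, wg.groups))
        for other in (res_perm, res_scaled):
            assert res.f_stat == pytest.approx(other.f_stat)
            assert res.p_value == pytest.approx(other.p_value)
            assert res.adj_r2 == pytest.approx(other.adj_r2)

    def test_perfect_separation_flagged(self):
        res = weighted_anova(_wg([0.1, 0.1, 0.9, 0.9], [1, 1, 1, 1],
                                 ["EUR", "EUR", "EAS", "EAS"], order=("EUR", "EAS")))
        assert res.perfect_separation and res.p_value == 0.0

    def test_requires_more_sets_than_groups(self):
        with pytest.raises(DataValidationError):
            weighted_anova(_wg([0.1, 0.2], [1, 1], ["EUR", "EAS"], order=("EUR", "EAS")))

    def test_null_simulation_type_one_error_calibrated(self):
        """Balding-Nichols null (theta=0.05, 20 sets/group, equal cohorts):
        rejection rate at alpha=0.05 stays within 0.05 +/- 0.02."""
        rng = np.random.default_rng(424242)
        theta, p0, reps = 0.05, 0.5, 2000
        a = p0 * (1 - theta) / theta
        b = (1 - p0) * (1 - theta) / theta
        g = np.repeat(["EUR", "EAS", "AFR"], 20)
        w = np.full(60, 100.0)
        rejections = 0
        for _ in range(reps):
            y = rng.beta(a, b, 60)
            rejections += weighted_anova(_wg(y, w, g)).p_value < 0.05
        assert abs(rejections / reps - 0.05) <= 0.02


class TestConfidenceIntervals:
    def test_interval_symmetric_and_bracketing(self, rng):
        res = weighted_anova(_random_instance(rng))
        for g in res.group_order:
            lo, hi = group_confidence_interval(res, g)
            m = res.group_means[g]
            assert lo < m < hi
            assert (m - lo) == pytest.approx(hi - m)

    def test_boundary_mean_interval_can_go_negative(self):
        # a group pinned at frequency 0 with pooled spread from other groups
        y = [0.0, 0.0, 0.0, 0.2, 0.4, 0.3, 0.5, 0.7, 0.6]
        g = ["EUR"] * 3 + ["EAS"] * 3 + ["AFR"] * 3
        res = weighted_anova(_wg(y, np.ones(9), g))
        lo, hi = group_confidence_interval(res, "EUR")
        assert lo < 0.0 < hi

    def test_degenerate_when_msw_zero(self):
        res = weighted_anova(_wg([0.1, 0.1, 0.9, 0.9], [1, 1, 1, 1],
                                 ["EUR", "EUR", "EAS", "EAS"], order=("EUR", "EAS")))
        assert group_confidence_interval(res, "EUR") == (0.1, 0.1)

    def test_widens_monotonically_with_level(self, rng):
        res = weighted_anova(_random_instance(rng))
        widths = [
            np.diff(group_confidence_interval(res, "EUR", level=lv))[0]
            for lv in (0.90, 0.95, 0.99)
        ]
        assert widths[0] < widths[1] < widths[2]


class TestTukeyKramer:
    def test_equal_means_give_p_one(self):
        res = weighted_anova(_wg([0.5, 0.5, 0.5, 0.5, 0.1, 0.9],
                                 np.ones(6),
                                 ["EUR", "EUR", "EAS", "EAS", "AFR", "AFR"]))
        assert tukey_kramer(res)[("EUR", "EAS")] == pytest.approx(1.0)

    def test_two_groups_equal_pooled_t_test(self, rng):
        """k=2: studentized-range p == two-sided pooled t p (q = t*sqrt(2))."""
        for _ in range(10):
            y = rng.uniform(0, 1, 14)
            wg = _wg(y, np.ones(14), ["EUR"] * 7 + ["EAS"] * 7, order=("EUR", "EAS"))
            p_tukey = tukey_kramer(weighted_anova(wg))[("EUR", "EAS")]
            _, p_t = stats.ttest_ind(y[:7], y[7:])
            assert p_tukey == pytest.approx(p_t, abs=1e-10)

    def test_balanced_case_matches_statsmodels(self, rng):
        """Independent reference: statsmodels pairwise_tukeyhsd, 50 instances."""
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        for _ in range(50):
            y = rng.normal(0.5, 0.1, 18)
            g = np.repeat(["EUR", "EAS", "AFR"], 6)
            res = weighted_anova(_wg(y, np.ones(18), g))
            ours = tukey_kramer(res)
            ref = pairwise_tukeyhsd(y, g)
            ref_p = {
                frozenset((row[0], row[1])): p
                for row, p in zip(ref._results_table.data[1:], ref.pvalues)
            }
            for (a, b), p in ours.items():
                assert p == pytest.approx(ref_p[frozenset((a, b))], abs=1e-4)

    def test_monotone_in_mean_separation(self):
        base = np.array([0.40, 0.42, 0.38, 0.60, 0.62, 0.58, 0.50, 0.52, 0.48])
        g = ["EUR"] * 3 + ["EAS"] * 3 + ["AFR"] * 3
        last_p = 1.1
        for shift in (0.0, 0.1, 0.2, 0.3):
            y = base.copy()
            y[3:6] += shift
            res = weighted_anova(_wg(y, np.ones(9), g))
            p = tukey_kramer(res)[("EUR", "EAS")]
            assert p < last_p
            last_p = p


class TestBonferroniAndLetters:
    def test_strict_inequality_at_thresholds(self):
        thresholds = SignificanceThresholds()
        assoc, pairs = apply_bonferroni(
            0.001, {("EUR", "EAS"): 0.0001, ("EUR", "AFR"): 3.18e-12,
                    ("EAS", "AFR"): 3.85e-2}, thresholds
        )
        assert not assoc  # 0.001 is not < 0.001
        assert not pairs[("EUR", "EAS")]
        assert pairs[("EUR", "AFR")]
        assert not pairs[("EAS", "AFR")]

    def test_all_pairs_significant_gives_distinct_letters(self):
        p = {("EUR", "EAS"): 0.0, ("EUR", "AFR"): 0.0, ("EAS", "AFR"): 0.0}
        letters = compact_letter_display(p)
        assert len({letters[g] for g in letters}) == 3

    def test_no_pair_significant_shares_one_letter(self):
        p = {("EUR", "EAS"): 0.5, ("EUR", "AFR"): 0.5, ("EAS", "AFR"): 0.5}
        assert set(compact_letter_display(p).values()) == {"a"}

    def test_published_style_pairing(self):
        # EAS ~ AFR, both differ from EUR -> EAS and AFR share a letter
        p = {("EUR", "EAS"): 1e-9, ("EUR", "AFR"): 1e-9, ("EAS", "AFR"): 0.2}
        letters = compact_letter_display(p)
        assert letters["EAS"] == letters["AFR"]
        assert not set(letters["EUR"]) & set(letters["EAS"])

    @given(st.tuples(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1)))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_letter_sharing_encodes_nonsignificance(self, ps):
        """For k=3, sharing a letter <=> pairwise p >= alpha, always."""
        pairs = dict(zip([("EUR", "EAS"), ("EUR", "AFR"), ("EAS", "AFR")], ps))
        letters = compact_letter_display(pairs, alpha=0.05)
        for (a, b), p in pairs.items():
            share = bool(set(letters[a]) & set(letters[b]))
            assert share == (p >= 0.05)
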