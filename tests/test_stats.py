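"""Regression families, ANOVA/Tukey-Kramer, Lilliefors, delta report."""

import numpy as np
import pytest
from scipy import stats as sps

from rflpdelta import (
    delta_report,
    fit_regression,
    lilliefors,
    tukey_kramer,
    unbalanced_anova,
)
from rflpdelta.stats import best_fit


class TestRegression:
    def test_exact_logarithmic(self):
        x = np.arange(5, 51, 5)
        fit = fit_regression(x, 2 * np.log(x) + 1, "logarithmic")
        assert fit.a == pytest.approx(2) and fit.b == pytest.approx(1)
        assert fit.r_squared == pytest.approx(1)
        assert fit.r_squared_linearized == pytest.approx(1)

    def test_exact_geometric_power_law(self):
        x = np.array([1, 2, 3, 4])
        fit = fit_regression(x, 3.0 * x**2, "geometric")
        assert fit.a == pytest.approx(3) and fit.b == pytest.approx(2)
        assert fit.r_squared == pytest.approx(1)

    @pytest.mark.parametrize(
        "family, a, b, make_y",
        [
            ("linear", 1.7, -4.0, lambda x, a, b: a * x + b),
            ("logarithmic", 5.5, 2.0, lambda x, a, b: a * np.log(x) + b),
            ("exponential", 2.0, 0.08, lambda x, a, b: a * np.exp(b * x)),
            ("geometric", 0.9, 0.55, lambda x, a, b: a * x**b),
        ],
    )
    def test_noiseless_parameter_recovery(self, family, a, b, make_y):
        x = np.arange(5, 51, 5, dtype=float)
        fit = fit_regression(x, make_y(x, a, b), family)
        assert fit.a == pytest.approx(a, rel=0.05)
        assert fit.b == pytest.approx(b, rel=0.05)

    def test_noisy_logarithmic_matches_generic_least_squares(self, rng):
        x = np.arange(5, 51, 5, dtype=float)
        y = 12.5 * np.log(x) + 3 + rng.normal(0, 1.5, size=len(x))
        fit = fit_regression(x, y, "logarithmic")
        ref = sps.linregress(np.log(x), y)
        assert fit.a == pytest.approx(ref.slope)
        assert fit.b == pytest.approx(ref.intercept)
        # within 2 SE of the oracle fit, and linearized R2 = r^2 identity
        assert abs(fit.a - ref.slope) <= 2 * ref.stderr
        assert fit.r_squared_linearized == pytest.approx(ref.rvalue**2)

    def test_positivity_preconditions(self):
        with pytest.raises(ValueError):
            fit_regression([0, 1, 2], [1, 2, 3], "logarithmic")
        with pytest.raises(ValueError):
            fit_regression([1, 2, 3], [-1, 2, 3], "exponential")

    def test_nonlinear_refinement_close_to_loglinear_on_clean_data(self):
        x = np.arange(1.0, 9.0)
        y = 2.0 * x**1.5
        lin = fit_regression(x, y, "geometric")
        non = fit_regression(x, y, "geometric", nonlinear=True)
        assert non.a == pytest.approx(lin.a, rel=1e-4)
        assert non.b == pytest.approx(lin.b, rel=1e-4)

    def test_best_fit_prefers_true_family(self, rng):
        x = np.arange(5, 51, 5, dtype=float)
        y = 12.5 * np.log(x) + 3 + rng.normal(0, 0.2, size=len(x))
        assert best_fit(x, y).family == "logarithmic"


class TestAnova:
    def test_identical_groups(self):
        res = unbalanced_anova([[1, 2, 3], [1, 2, 3]])
        assert res.f_statistic == pytest.approx(0)
        assert res.p_value == pytest.approx(1)

    def test_two_groups_equals_t_squared(self, rng):
        for _ in range(100):
            g1 = rng.normal(0, 1, rng.integers(3, 12))
            g2 = rng.normal(rng.normal(), 1, rng.integers(3, 12))
            res = unbalanced_anova([g1, g2])
            t, pt = sps.ttest_ind(g1, g2, equal_var=True)
            assert res.f_statistic == pytest.approx(t**2)
            assert res.p_value == pytest.approx(pt)

    def test_unbalanced_design_matches_hand_sums_of_squares(self, rng):
        ns = (10, 10, 7, 6, 6)
        groups = [rng.normal(m, 1.0, n) for m, n in zip((0, 0.5, 1, 2, 8), ns)]
        res = unbalanced_anova(groups)
        allv = np.concatenate(groups)
        grand = allv.mean()
        ssb = sum(n * (g.mean() - grand) ** 2 for g, n in zip(groups, ns))
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_hand = (ssb / (len(ns) - 1)) / (ssw / (len(allv) - len(ns)))
        assert res.f_statistic == pytest.approx(f_hand)
        assert (res.df_between, res.df_within) == (4, len(allv) - 5)
        assert res.group_ns == list(ns)


class TestTukeyKramer:
    def test_identical_groups_nothing_significant(self):
        res = tukey_kramer([[1.0, 2, 3, 4]] * 3)
        assert res.significant_pairs() == []

    def test_extreme_separation_is_significant(self, rng):
        g1 = rng.normal(0, 1, 8)
        g2 = rng.normal(100, 1, 6)
        res = tukey_kramer([g1, g2], labels=["lo", "hi"])
        assert res.significant_pairs() == [("lo", "hi")]

    def test_q_statistics_match_direct_formula(self, rng):
        groups = [rng.normal(m, 1, 9) for m in (0.0, 0.4, 1.2)]
        res = tukey_kramer(groups)
        msw = np.mean([np.var(g, ddof=1) for g in groups])  # balanced: mean of variances
        for pair, (i, j) in zip(res.pairs, [(0, 1), (0, 2), (1, 2)]):
            se = np.sqrt(msw / 2 * (1 / 9 + 1 / 9))
            q = abs(groups[i].mean() - groups[j].mean()) / se
            assert pair.q_statistic == pytest.approx(q)

    def test_agrees_with_statsmodels_tukeyhsd(self, rng):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        groups = [rng.normal(m, 1, n) for m, n in ((0, 10), (1, 7), (3, 5))]
        values = np.concatenate(groups)
        labels = np.repeat(["a", "b", "c"], [10, 7, 5])
        sm = pairwise_tukeyhsd(values, labels, alpha=0.05)
        ours = tukey_kramer(groups, labels=["a", "b", "c"])
        assert [p.significant for p in ours.pairs] == list(sm.reject)
        np.testing.assert_allclose(
            [p.p_value for p in ours.pairs], sm.pvalues, atol=1e-4
        )


class TestLilliefors:
    def test_high_power_against_uniform(self):
        x = np.random.default_rng(11).uniform(0, 1, 200)
        d, p = lilliefors(x, seed=0)
        assert p < 0.05

    def test_normal_samples_rejected_at_nominal_rate(self):
        rejections = 0
        for i in range(500):
            x = np.random.default_rng(1000 + i).normal(3.0, 2.0, 100)
            _, p = lilliefors(x, seed=0)
            rejections += p < 0.05
        # nominal 5%; band is ~2 binomial SE around it
        assert 0.03 <= rejections / 500 <= 0.07

    def test_constant_sample_rejected_as_input(self):
        with pytest.raises(ValueError):
            lilliefors([2.0, 2.0, 2.0, 2.0])

    def test_monte_carlo_agrees_with_published_table(self):
        x = np.random.default_rng(5).normal(0, 1, 40) ** 2  # skewed
        d_mc, p_mc = lilliefors(x, mode="monte_carlo", n_draws=20000, seed=0)
        d_tab, p_tab = lilliefors(x, mode="table")
        assert d_mc == pytest.approx(d_tab)
        # both modes must agree on the rejection decision
        assert (p_mc < 0.05) == (p_tab < 0.05)


class TestDeltaReport:
    def test_arithmetic_example(self):
        rep = delta_report({10: 40, 20: 60}, {10: 12, 20: 10})
        folds = dict(zip(rep.table["group_size"], rep.table["fold_loss"]))
        assert folds[10] == pytest.approx(40 / 12)
        assert folds[20] == pytest.approx(6.0)
        assert rep.fold_min == pytest.approx(40 / 12)
        assert rep.fold_max == pytest.approx(6.0)

    def test_identical_summaries_give_unit_folds(self):
        rep = delta_report({5: 10, 10: 20}, {5: 10, 10: 20})
        assert rep.fold_min == rep.fold_max == pytest.approx(1.0)

    def test_zero_actual_is_flagged_not_divided(self):
        rep = delta_report({5: 10, 10: 20}, {5: 0, 10: 5})
        assert rep.undefined_groups == [5]
        assert rep.fold_max == pytest.approx(4.0)

    def test_mismatched_group_sizes_rejected(self):
        with pytest.raises(ValueError):
            delta_report({5: 10}, {10: 5})
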