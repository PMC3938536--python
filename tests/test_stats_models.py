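import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ppa_speech.errors import ComputationError, ValidationError
from ppa_speech.stats_models import (
    MODEL1_COEFFICIENTS,
    MODEL2_COEFFICIENTS,
    anova_oneway,
    chi2_critical,
    collinearity_screen,
    duration_index,
    fit_dfa,
    mahalanobis_screen,
    median_test,
    moment_screen,
    silence_duration_index,
    tukey_kramer,
)


class TestMomentScreen:
    def test_symmetric_data_zero_skew(self):
        skew, _ = moment_screen([-1.0, 0.0, 1.0])
        assert skew == pytest.approx(0.0, abs=1e-12)

    def test_right_tail_positive_skew(self):
        skew, _ = moment_screen([0.0, 0.0, 0.0, 10.0])
        assert skew > 0

    def test_adjusted_excess_kurtosis_uniform_five(self):
        # independent hand computation of the adjusted Fisher formula:
        # m2 = 2, m4 = 6.8, g2 = 6.8/4 - 3 = -1.3,
        # G2 = ((n+1)*g2 + 6) * (n-1)/((n-2)*(n-3)) = (6*-1.3 + 6)*4/6 = -1.2
        _, kurt = moment_screen([1.0, 2.0, 3.0, 4.0, 5.0])
        assert kurt == pytest.approx(-1.2, abs=1e-12)

    def test_zero_variance(self):
        with pytest.raises(ComputationError):
            moment_screen([2.0, 2.0, 2.0])

    def test_too_few_points(self):
        with pytest.raises(ValidationError):
            moment_screen([1.0, 2.0])


class TestAnova:
    def test_identical_groups(self):
        f, df1, df2, p = anova_oneway([[1, 2, 3], [1, 2, 3]])
        assert f == pytest.approx(0.0, abs=1e-12)
        assert (df1, df2) == (1, 4)
        assert p == pytest.approx(1.0)

    def test_hand_computed_f(self):
        # MSB = 4 (df 1), MSW = 0.5 (df 2) -> F = 8
        f, df1, df2, p = anova_oneway([[1, 2], [3, 4]])
        assert f == pytest.approx(8.0, abs=1e-12)
        assert (df1, df2) == (1, 2)
        assert p == pytest.approx(float(sps.f.sf(8.0, 1, 2)))

    def test_group_order_invariance(self, rng):
        groups = [rng.normal(i, 1, 8).tolist() for i in range(3)]
        f1 = anova_oneway(groups)[0]
        f2 = anova_oneway(groups[::-1])[0]
        assert f1 == pytest.approx(f2, rel=1e-12)

    def test_degenerate(self):
        with pytest.raises(ComputationError):
            anova_oneway([[1.0, 1.0], [1.0, 1.0]])


class TestTukeyKramer:
    def test_identical_groups_not_significant(self):
        (cmp,) = tukey_kramer([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert cmp.q == pytest.approx(0.0, abs=1e-12)
        assert not cmp.significant

    def test_far_pair_flagged_close_pair_not(self, rng):
        groups = [
            rng.normal(0.0, 1.0, 10),
            rng.normal(0.3, 1.0, 10),
            rng.normal(8.0, 1.0, 10),
        ]
        comparisons = {(c.group_a, c.group_b): c for c in tukey_kramer(groups)}
        assert comparisons[(0, 2)].significant
        assert comparisons[(1, 2)].significant
        assert not comparisons[(0, 1)].significant

    def test_matches_scipy_tukey_hsd_equal_n(self, rng):
        groups = [rng.normal(m, 1.0, 12) for m in (0.0, 0.8, 2.0)]
        mine = {(c.group_a, c.group_b): c.p for c in tukey_kramer(groups)}
        ref = sps.tukey_hsd(*groups)
        for (i, j), p in mine.items():
            assert p == pytest.approx(float(ref.pvalue[i, j]), abs=1e-9)

    def test_matches_scipy_tukey_hsd_unequal_n(self, rng):
        groups = [rng.normal(0, 1, 6), rng.normal(1.2, 1, 11), rng.normal(2.5, 1, 8)]
        mine = {(c.group_a, c.group_b): c.p for c in tukey_kramer(groups)}
        ref = sps.tukey_hsd(*groups)
        for (i, j), p in mine.items():
            assert p == pytest.approx(float(ref.pvalue[i, j]), abs=1e-9)


def fisher_two_sided_oracle(table):
    """Enumeration oracle: sum hypergeometric probabilities <= observed."""
    a, b = table[0]
    c, d = table[1]
    row1, col1, n = a + b, a + c, a + b + c + d
    obs = sps.hypergeom.pmf(a, n, row1, col1)
    total = 0.0
    for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        p = sps.hypergeom.pmf(k, n, row1, col1)
        if p <= obs * (1 + 1e-9):
            total += p
    return total


class TestMedianTest:
    def test_interleaved_groups_p_one(self):
        res = median_test([[1.0, 3.0], [2.0, 4.0]])
        assert res.method == "fisher-exact"
        assert res.p == pytest.approx(1.0)
        np.testing.assert_array_equal(res.table, [[1, 1], [1, 1]])

    def test_maximal_separation_smallest_p(self):
        res = median_test([[1.0, 2.0], [9.0, 10.0]])
        np.testing.assert_array_equal(res.table, [[0, 2], [2, 0]])
        assert res.p == pytest.approx(fisher_two_sided_oracle(res.table))
        assert res.p == pytest.approx(1.0 / 3.0)  # smallest attainable for n = 4

    def test_exact_matches_enumeration_oracle(self, rng):
        for _ in range(10):
            g1 = rng.normal(0, 1, 6).tolist()
            g2 = rng.normal(0.8, 1, 5).tolist()
            res = median_test([g1, g2])
            if res.method == "fisher-exact":
                assert res.p == pytest.approx(fisher_two_sided_oracle(res.table))

    def test_within_group_permutation_invariance(self, rng):
        g1 = rng.normal(0, 1, 30).tolist()
        g2 = rng.normal(1, 1, 25).tolist()
        res1 = median_test([g1, g2])
        rng.shuffle(g1)
        rng.shuffle(g2)
        res2 = median_test([g1, g2])
        assert res1.p == res2.p

    def test_large_groups_use_chi_square(self, rng):
        res = median_test([rng.normal(0, 1, 40), rng.normal(1, 1, 40)])
        assert res.method == "chi-square"
        assert res.statistic is not None

    def test_all_equal(self):
        with pytest.raises(ComputationError):
            median_test([[1.0, 1.0], [1.0, 1.0]])


class TestCollinearityScreen:
    def test_duplicated_column_excluded(self, rng):
        x = rng.normal(0, 1, 50)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(0, 1, 50)})
        res = collinearity_screen(df, ["a", "b", "c"], drop_priority=("b",))
        assert res.excluded == ("b",)
        assert set(res.retained) == {"a", "c"}

    def test_independent_columns_none_excluded(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame(rng.normal(0, 1, (200, 4)), columns=list("abcd"))
            res = collinearity_screen(df, list("abcd"))
            assert res.excluded == ()

    def test_silence_scenario_drops_median_by_priority(self):
        # shared latent slowing makes median and MAD of silence durations
        # strongly correlated; the median column is dropped by priority
        rng = np.random.default_rng(7)
        latent = rng.gamma(4.0, 0.05, 60)
        df = pd.DataFrame(
            {
                "median_silence_s": latent + rng.normal(0, 0.01, 60),
                "mad_silence_s": 0.7 * latent + rng.normal(0, 0.01, 60),
                "pvi_dur_ws": rng.normal(100, 20, 60),
            }
        )
        r = df.corr().loc["median_silence_s", "mad_silence_s"]
        assert r > 0.80
        res = collinearity_screen(df, list(df.columns))
        assert res.excluded == ("median_silence_s",)
        assert "mad_silence_s" in res.retained

    def test_constant_predictor(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ComputationError, match="constant"):
            collinearity_screen(df, ["a", "b"])


class TestMahalanobis:
    def test_two_point_hand_computation(self):
        d2, flags, _ = mahalanobis_screen(np.array([[0.0], [2.0]]), alpha=0.5)
        np.testing.assert_allclose(d2, [0.5, 0.5])

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_sum_identity(self, seed):
        rng = np.random.default_rng(seed)
        n, p = int(rng.integers(8, 40)), int(rng.integers(1, 5))
        x = rng.normal(0, 1, (n, p))
        d2, _, _ = mahalanobis_screen(x)
        assert d2.sum() == pytest.approx(p * (n - 1), rel=1e-9)

    def test_planted_outlier_flagged(self):
        rng = np.random.default_rng(99)
        x = rng.normal(0, 1, (60, 4))
        x[17] = 10.0  # ~10 sigma on every axis
        d2, flags, critical = mahalanobis_screen(x, alpha=0.001)
        assert flags[17]
        assert flags.sum() == 1
        assert critical == pytest.approx(18.4668, abs=1e-3)

    def test_singular_covariance(self):
        x = np.column_stack([np.arange(10.0), np.arange(10.0)])
        with pytest.raises((ComputationError, ValidationError)):
            mahalanobis_screen(x)


class TestChi2Critical:
    def test_printed_screening_constant(self):
        assert round(chi2_critical(4, 0.001), 2) == 18.47

    def test_df1_alpha05_closed_form(self):
        # chi2(1) upper 5% equals the squared two-sided normal quantile
        assert chi2_critical(1, 0.05) == pytest.approx(sps.norm.ppf(0.975) ** 2, abs=1e-9)
        assert chi2_critical(1, 0.05) == pytest.approx(3.841, abs=5e-4)

    def test_chi2_2_median_is_ln4(self):
        assert chi2_critical(2, 0.5) == pytest.approx(math.log(4.0), abs=1e-12)

    @given(df=st.integers(min_value=1, max_value=30))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_df_and_alpha(self, df):
        assert chi2_critical(df + 1, 0.01) > chi2_critical(df, 0.01)
        assert chi2_critical(df, 0.001) > chi2_critical(df, 0.01)

    def test_domain(self):
        with pytest.raises(ValidationError):
            chi2_critical(0, 0.05)
        with pytest.raises(ValidationError):
            chi2_critical(3, 1.5)


def normal_equations_oracle(x, y):
    """Brute-force OLS via the normal equations and textbook formulas."""
    design = np.column_stack([np.ones(len(y)), x])
    xtx = design.T @ design
    coef = np.linalg.solve(xtx, design.T @ y)
    resid = y - design @ coef
    dfres = len(y) - design.shape[1]
    s2 = float(resid @ resid) / dfres
    se = np.sqrt(np.diag(s2 * np.linalg.inv(xtx)))
    r2 = 1 - float(resid @ resid) / float(((y - y.mean()) ** 2).sum())
    return coef, se, r2


class TestFitDFA:
    def test_hand_computed_simple_regression(self):
        fit = fit_dfa(np.array([1.0, 2.0, 3.0, 4.0]), [0, 0, 1, 1])
        assert fit.b[0] == pytest.approx(0.4)
        assert fit.constant == pytest.approx(-0.5)
        assert fit.r2 == pytest.approx(0.8)

    def test_affine_shift_changes_only_intercept(self, rng):
        x = rng.normal(0, 1, (30, 2))
        y = rng.integers(0, 2, 30).astype(float)
        f1 = fit_dfa(x, y)
        f2 = fit_dfa(x + np.array([5.0, -3.0]), y)
        np.testing.assert_allclose(f1.b, f2.b, atol=1e-10)
        assert f2.constant == pytest.approx(f1.constant - 5 * f1.b[0] + 3 * f1.b[1])

    def test_r2_equals_squared_correlation(self, rng):
        x = rng.normal(0, 1, (40, 3))
        y = (x[:, 0] + rng.normal(0, 1, 40) > 0).astype(float)
        fit = fit_dfa(x, y)
        fitted = fit.constant + x @ fit.b
        assert fit.r2 == pytest.approx(np.corrcoef(fitted, y)[0, 1] ** 2, rel=1e-9)

    def test_matches_normal_equations_oracle(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(8, 51))
            p = int(rng.integers(1, 4))
            x = rng.normal(0, 1, (n, p))
            y = rng.integers(0, 2, n).astype(float)
            if y.std() == 0:
                y[0] = 1 - y[0]
            fit = fit_dfa(x, y)
            coef, se, r2 = normal_equations_oracle(x, y)
            np.testing.assert_allclose(np.r_[fit.constant, fit.b], coef, atol=1e-8)
            np.testing.assert_allclose(np.r_[fit.constant_se, fit.se], se, atol=1e-8)
            assert fit.r2 == pytest.approx(r2, abs=1e-8)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        x = rng.normal(0, 1, (25, 2))
        y = rng.integers(0, 2, 25).astype(float)
        fit = fit_dfa(x, y)
        ref = sm.OLS(y, sm.add_constant(x)).fit()
        np.testing.assert_allclose(np.r_[fit.constant, fit.b], ref.params, atol=1e-10)
        np.testing.assert_allclose(np.r_[fit.constant_se, fit.se], ref.bse, atol=1e-10)
        np.testing.assert_allclose(np.r_[fit.constant_p, fit.p], ref.pvalues, atol=1e-10)
        assert fit.r2 == pytest.approx(ref.rsquared, abs=1e-12)

    def test_standardized_coefficients(self, rng):
        x = rng.normal(0, 2, (30, 2))
        y = rng.integers(0, 2, 30).astype(float)
        fit = fit_dfa(x, y)
        expected = fit.b * x.std(axis=0, ddof=1) / y.std(ddof=1)
        np.testing.assert_allclose(fit.beta, expected)

    def test_dataframe_with_group_labels(self):
        df = pd.DataFrame(
            {
                "group": ["lvPPA", "lvPPA", "nfvPPA", "nfvPPA"],
                "x": [1.0, 2.0, 3.0, 4.0],
            }
        )
        fit = fit_dfa(df, "group", ["x"])
        assert fit.b[0] == pytest.approx(0.4)

    def test_rank_deficiency(self):
        x = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(ComputationError, match="rank"):
            fit_dfa(x, np.r_[np.zeros(5), np.ones(5)])

    def test_too_few_rows(self):
        with pytest.raises(ValidationError):
            fit_dfa(np.ones((3, 2)) + np.arange(6).reshape(3, 2), [0.0, 1.0, 0.0])


class TestDiagnosticIndices:
    def test_model2_lv_group_medians(self):
        res = duration_index(116.2, 89.6)
        assert res.index == pytest.approx(0.2062, abs=1e-4)
        assert res.class_code == 0
        assert res.label == "lvPPA"

    def test_model2_nfv_group_medians(self):
        res = duration_index(87.4, 63.9)
        assert res.index == pytest.approx(0.6165, abs=1e-4)
        assert res.class_code == 1
        assert res.label == "nfvPPA"

    def test_model2_zero_pvis_maximally_apraxic(self):
        res = duration_index(0.0, 0.0)
        assert res.index == pytest.approx(1.763)
        assert res.class_code == 1

    def test_model2_monotone_nonincreasing(self):
        base = duration_index(80.0, 60.0).index
        assert duration_index(90.0, 60.0).index < base
        assert duration_index(80.0, 70.0).index < base

    def test_model2_negative_input_rejected(self):
        with pytest.raises(ValidationError):
            duration_index(-87.4, 63.9)

    def test_half_rounds_away_from_zero(self):
        coefs = {"constant": 0.5, "pvi_dur_ws": 0.0, "pvi_dur_sw": 0.0}
        res = duration_index(10.0, 10.0, coefs)
        assert res.index == 0.5
        assert res.class_code == 1
        # negative halves round away from zero, then clamp to 0
        coefs["constant"] = -0.5
        assert duration_index(10.0, 10.0, coefs).class_code == 0

    def test_model1_lv_group_means(self):
        res = silence_duration_index(0.61, 0.0865, 116.2)
        assert res.index == pytest.approx(0.229, abs=1e-3)
        assert res.class_code == 0

    def test_model1_nfv_group_means(self):
        res = silence_duration_index(0.62, 0.1586, 87.4)
        assert res.index == pytest.approx(0.712, abs=1e-3)
        assert res.class_code == 1

    def test_model1_all_zero_inputs(self):
        res = silence_duration_index(0.0, 0.0, 0.0)
        assert res.index == pytest.approx(2.387)
        assert res.class_code == 1

    def test_model1_unit_check_warning(self):
        with pytest.warns(UserWarning, match="milliseconds"):
            silence_duration_index(0.6, 158.6, 87.4)

    def test_model1_arcsin_domain(self):
        with pytest.raises(ValidationError):
            silence_duration_index(2.0, 0.1, 87.4)

    def test_printed_coefficients_exposed(self):
        assert MODEL2_COEFFICIENTS["constant"] == 1.763
        assert MODEL1_COEFFICIENTS["mad_silence_s"] == 2.991
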