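"""Dose-response models: exact OLS recovery, spline basis oracle, Wald tests."""

import numpy as np
import pandas as pd
import pytest

from sleepbioage.association import (
    bonferroni_threshold,
    fit_category_model,
    fit_rcs,
    fit_trend_model,
    rcs_basis,
    interaction_wald_test,
)
from sleepbioage.exposure import CovariateSpec, categorize_sleep_durations

NO_COVARIATES = CovariateSpec(continuous=[], binary=[], categorical={})


def cohort_from_hours(hours, y, **extra):
    t = pd.DataFrame({"sleep_hours": np.asarray(hours, dtype=float), "y": y, **extra})
    t["sleep_category"] = categorize_sleep_durations(t["sleep_hours"])
    return t


class TestCategoryModel:
    def test_noiseless_offsets_recovered_exactly(self):
        rng = np.random.default_rng(1)
        n = 400
        hours = rng.choice([5.0, 6.0, 7.0, 8.0, 9.0], size=n)
        age = rng.uniform(40, 70, n)
        offsets = {"le5": 0.8, "6": 0.25, "7": 0.0, "8": 0.3, "ge9": 0.9}
        cats = [("le5" if h == 5 else "ge9" if h == 9 else str(int(h))) for h in hours]
        y = np.array([offsets[c] for c in cats]) + 0.05 * age + 2.0
        t = cohort_from_hours(hours, y, age=age)
        spec = CovariateSpec(continuous=["age"], binary=[], categorical={})
        res = fit_category_model(t, "y", spec)
        for cat, off in offsets.items():
            assert res.term(f"sleep[{cat}]")["beta"] == pytest.approx(off, abs=1e-9)
        assert res.term("age")["beta"] == pytest.approx(0.05, abs=1e-9)

    def test_matches_normal_equations_on_toy_data(self):
        hours = [5.0, 6.0, 7.0, 8.0, 9.0, 7.0, 6.0, 8.0]
        y = [3.1, 2.0, 1.2, 2.5, 3.9, 1.0, 2.2, 2.7]
        t = cohort_from_hours(hours, y)
        res = fit_category_model(t, "y", NO_COVARIATES)
        # explicit normal-equations oracle
        X = np.column_stack(
            [
                np.ones(8),
                [h == 5 for h in hours],
                [h == 6 for h in hours],
                [h == 8 for h in hours],
                [h == 9 for h in hours],
            ]
        ).astype(float)
        beta = np.linalg.solve(X.T @ X, X.T @ np.asarray(y))
        assert res.term("sleep[le5]")["beta"] == pytest.approx(beta[1], abs=1e-8)
        assert res.term("sleep[6]")["beta"] == pytest.approx(beta[2], abs=1e-8)
        assert res.term("sleep[8]")["beta"] == pytest.approx(beta[3], abs=1e-8)
        assert res.term("sleep[ge9]")["beta"] == pytest.approx(beta[4], abs=1e-8)

    def test_reference_category_is_exact_zero(self):
        rng = np.random.default_rng(2)
        hours = rng.choice([5.0, 6, 7, 8, 9], size=100)
        t = cohort_from_hours(hours, rng.normal(size=100))
        res = fit_category_model(t, "y", NO_COVARIATES)
        assert res.term("sleep[7]")["beta"] == 0.0

    def test_ci_is_beta_plus_minus_196_se(self):
        rng = np.random.default_rng(3)
        hours = rng.choice([5.0, 6, 7, 8, 9], size=200)
        t = cohort_from_hours(hours, rng.normal(size=200))
        res = fit_category_model(t, "y", NO_COVARIATES)
        row = res.term("sleep[6]")
        assert row["ci_low"] == pytest.approx(row["beta"] - 1.96 * row["se"], abs=1e-4)

    def test_collinear_design_reported(self):
        rng = np.random.default_rng(4)
        hours = rng.choice([5.0, 6, 7, 8, 9], size=60)
        t = cohort_from_hours(hours, rng.normal(size=60))
        t["dup"] = 1.0  # collinear with the intercept
        spec = CovariateSpec(continuous=["dup"], binary=[], categorical={})
        with pytest.raises(ValueError, match="rank"):
            fit_category_model(t, "y", spec)


class TestTrendModel:
    def test_monotone_outcome_gives_positive_significant_slope(self):
        rng = np.random.default_rng(5)
        hours = rng.choice([5.0, 6, 7, 8, 9], size=2000)
        y = hours + rng.normal(0, 0.5, size=2000)
        res = fit_trend_model(cohort_from_hours(hours, y), "y", NO_COVARIATES)
        row = res.term("sleep_trend")
        assert row["beta"] > 0
        assert row["p"] < 1e-10

    def test_symmetric_u_has_zero_trend(self):
        # balanced categories, outcome symmetric around 7 h -> exact zero slope
        hours = np.repeat([5.0, 6.0, 7.0, 8.0, 9.0], 20)
        y = (hours - 7.0) ** 2
        res = fit_trend_model(cohort_from_hours(hours, y), "y", NO_COVARIATES)
        assert res.term("sleep_trend")["beta"] == pytest.approx(0.0, abs=1e-10)

    def test_category_medians_on_integer_hours(self):
        hours = np.repeat([5.0, 6.0, 7.0, 8.0, 9.0], 4)
        res = fit_trend_model(
            cohort_from_hours(hours, np.arange(20.0)), "y", NO_COVARIATES
        )
        assert res.extras["category_medians"] == {
            "le5": 5.0, "6": 6.0, "7": 7.0, "8": 8.0, "ge9": 9.0
        }


class TestRCS:
    def test_basis_matches_textbook_truncated_power_oracle(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(3, 11, 200)
        knots = (5.0, 7.0, 9.5)
        got = rcs_basis(x, knots)
        t1, t2, t3 = knots

        def pos3(v):
            return np.where(v > 0, v, 0.0) ** 3

        nonlin = (
            pos3(x - t1)
            - pos3(x - t2) * (t3 - t1) / (t3 - t2)
            + pos3(x - t3) * (t2 - t1) / (t3 - t2)
        ) / (t3 - t1) ** 2
        assert got.shape == (200, 2)  # 3 knots -> exactly 2 columns
        np.testing.assert_allclose(got[:, 0], x, atol=1e-12)
        np.testing.assert_allclose(got[:, 1], nonlin, atol=1e-10)

    def test_linear_beyond_boundary_knots(self):
        knots = (5.0, 7.0, 9.0)
        x = np.array([9.0, 10.0, 11.0, 12.0])
        B = rcs_basis(x, knots)
        # second differences of the nonlinear column vanish outside the knots
        d2 = np.diff(B[:, 1], 2)
        np.testing.assert_allclose(d2, 0.0, atol=1e-10)

    def test_linear_truth_yields_straight_curve_and_null_nonlinearity(self):
        rng = np.random.default_rng(7)
        hours = rng.choice([4, 5, 5.5, 6, 6.5, 7, 7.5, 8, 8.5, 9, 10], size=3000)
        y = 1.5 * hours + rng.normal(0, 0.3, 3000)
        fit = fit_rcs(cohort_from_hours(hours, y), "y", NO_COVARIATES)
        # nonlinear coefficient indistinguishable from zero
        z = fit.coefficients[1] / np.sqrt(fit.covariance[1, 1])
        assert abs(z) < 4
        # predicted curve is a straight line through the reference
        slope = np.polyfit(fit.curve["hours"], fit.curve["estimate"], 1)[0]
        resid = fit.curve["estimate"] - slope * (fit.curve["hours"] - 7.0)
        np.testing.assert_allclose(resid, resid.mean(), atol=0.05)

    def test_u_shaped_truth_flags_nonlinearity(self):
        rng = np.random.default_rng(8)
        hours = rng.choice([5.0, 6, 6.5, 7, 7.5, 8, 9], size=2000)
        y = 0.5 * (hours - 7.0) ** 2 + rng.normal(0, 0.5, 2000)
        fit = fit_rcs(cohort_from_hours(hours, y), "y", NO_COVARIATES)
        assert fit.p_nonlinear < 1e-6
        assert fit.p_overall < 1e-6

    def test_curve_anchored_at_reference(self):
        rng = np.random.default_rng(9)
        hours = rng.choice([5.0, 6, 7, 8, 9], size=500)
        y = (hours - 7.0) ** 2 + rng.normal(0, 0.5, 500)
        grid = np.array([5.0, 6.0, 7.0, 8.0, 9.0])
        fit = fit_rcs(cohort_from_hours(hours, y), "y", NO_COVARIATES, grid=grid)
        assert fit.curve.set_index("hours").loc[7.0, "estimate"] == pytest.approx(0.0, abs=1e-12)

    def test_changing_reference_shifts_curve_by_constant(self):
        rng = np.random.default_rng(10)
        hours = rng.choice([5.0, 6, 7, 8, 9], size=500)
        y = (hours - 7.0) ** 2 + rng.normal(0, 0.5, 500)
        t = cohort_from_hours(hours, y)
        grid = np.linspace(5, 9, 9)
        a = fit_rcs(t, "y", NO_COVARIATES, reference_hours=7.0, grid=grid)
        b = fit_rcs(t, "y", NO_COVARIATES, reference_hours=8.0, grid=grid)
        diff = a.curve["estimate"] - b.curve["estimate"]
        np.testing.assert_allclose(diff, diff.iloc[0], atol=1e-10)

    def test_tied_hours_fall_back_to_distinct_knots(self):
        # 10th and 50th percentiles coincide on this heavily tied sample
        hours = np.array([6.0] * 70 + [5.0] * 5 + [7.0] * 15 + [8.0] * 10)
        rng = np.random.default_rng(11)
        y = rng.normal(size=len(hours))
        fit = fit_rcs(cohort_from_hours(hours, y), "y", NO_COVARIATES)
        assert len(set(fit.knots)) == 3


class TestInteraction:
    def _stratified(self, n, effect_b, seed=12):
        rng = np.random.default_rng(seed)
        hours = rng.choice([5.0, 6, 7, 8, 9], size=n)
        stratum = rng.choice(["A", "B"], size=n)
        base = 0.5 * (hours - 7.0) ** 2
        y = np.where(stratum == "B", effect_b * base, base) + rng.normal(0, 0.5, n)
        return cohort_from_hours(hours, y, stratum=stratum)

    def test_single_stratum_rejected(self):
        t = self._stratified(200, 1.0)
        t["stratum"] = "A"
        with pytest.raises(ValueError, match="strata"):
            interaction_wald_test(t, "y", "stratum", NO_COVARIATES)

    def test_empty_cell_reported(self):
        t = self._stratified(200, 1.0)
        t = t.loc[~((t["stratum"] == "B") & (t["sleep_category"] == "le5"))]
        with pytest.raises(ValueError, match="empty"):
            interaction_wald_test(t, "y", "stratum", NO_COVARIATES)

    def test_doubled_effect_detected(self):
        t = self._stratified(4000, 2.0)
        p, per = interaction_wald_test(t, "y", "stratum", NO_COVARIATES)
        assert p < 1e-4
        assert set(per) == {"A", "B"}
        # stratum B's extreme-category contrast is roughly doubled
        bA = per["A"].term("sleep[le5]")["beta"]
        bB = per["B"].term("sleep[le5]")["beta"]
        assert bB > 1.4 * bA

    def test_identical_effects_yield_large_p(self):
        t = self._stratified(4000, 1.0)
        p, _ = interaction_wald_test(t, "y", "stratum", NO_COVARIATES)
        assert p > 0.01


def test_bonferroni_gate_is_point_zero_one_for_five_outcomes():
    assert bonferroni_threshold(5) == pytest.approx(0.01)
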