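"""PhenoAge: Gompertz fitting, penalty limits, age-scale calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from sleepbioage.bioage import fit_phenoage, score_phenoage
from sleepbioage.bioage.phenoage import PhenoAgeModel, gompertz_loglik, mortality_risk
from sleepbioage.panel import Analyte, BiomarkerPanel


def simulate_gompertz(n, seed, b0, b_age, coefs, gamma, horizon=27.0):
    """Independent simulation from a known Gompertz PH model."""
    rng = np.random.default_rng(seed)
    age = rng.uniform(40, 70, n)
    X = rng.normal(0, 1, size=(n, len(coefs)))
    lp = b0 + b_age * age + X @ np.asarray(coefs)
    u = rng.uniform(size=n)
    t = np.log1p(-gamma * np.log(u) * np.exp(-lp)) / gamma
    table = pd.DataFrame({"age": age})
    for j in range(len(coefs)):
        table[f"m{j+1}"] = X[:, j]
    table["follow_up_years"] = np.minimum(t, horizon)
    table["death"] = (t <= horizon).astype(int)
    return table


def small_panel(p):
    return BiomarkerPanel(tuple(Analyte(f"m{j+1}", "u") for j in range(p)))


@pytest.fixture(scope="module")
def gompertz_data():
    return simulate_gompertz(
        5000, seed=8, b0=-9.5, b_age=0.09, coefs=[0.3, -0.2, 0.15], gamma=0.08
    )


class TestFit:
    def test_zero_penalty_matches_independent_mle(self, gompertz_data):
        """As the penalty vanishes the elastic-net fit must coincide with an
        independently optimized unpenalized maximum-likelihood fit."""
        panel = small_panel(3)
        model = fit_phenoage(gompertz_data, panel, penalty_strength=0.0)

        time = gompertz_data["follow_up_years"].to_numpy()
        event = gompertz_data["death"].to_numpy(float)
        Z = np.column_stack(
            [
                (gompertz_data[n] - gompertz_data[n].mean()) / gompertz_data[n].std()
                for n in panel.names
            ]
        )
        X = np.column_stack([np.ones(len(time)), gompertz_data["age"], Z])

        # independent oracle: Nelder-Mead on the raw likelihood
        def neg_ll(params):
            return -gompertz_loglik(params[:-1], np.exp(params[-1]), X, time, event)

        start = np.r_[np.zeros(X.shape[1]), np.log(0.05)]
        start[0] = -8.0
        oracle = optimize.minimize(neg_ll, start, method="Nelder-Mead",
                                   options={"maxiter": 40000, "xatol": 1e-8,
                                            "fatol": 1e-10, "adaptive": True})
        fitted = np.r_[
            model.intercept,
            model.age_coefficient,
            [model.coefficients[n] for n in panel.names],
            model.gamma,
        ]
        expected = np.r_[oracle.x[:-1], np.exp(oracle.x[-1])]
        np.testing.assert_allclose(fitted, expected, rtol=1e-4, atol=1e-6)

    def test_heavy_penalty_shrinks_biomarkers_not_age(self, gompertz_data):
        model = fit_phenoage(gompertz_data, small_panel(3), penalty_strength=1e4)
        for v in model.coefficients.values():
            assert abs(v) < 1e-3
        assert model.age_coefficient > 0.01

    def test_coefficient_recovery_within_3_se(self, gompertz_data):
        """At n = 5000 the unpenalized fit recovers the generative
        coefficients within 3 standard errors (numeric-Hessian SEs)."""
        panel = small_panel(3)
        model = fit_phenoage(gompertz_data, panel, penalty_strength=0.0)
        time = gompertz_data["follow_up_years"].to_numpy()
        event = gompertz_data["death"].to_numpy(float)
        Z = np.column_stack(
            [
                (gompertz_data[n] - gompertz_data[n].mean()) / gompertz_data[n].std()
                for n in panel.names
            ]
        )
        X = np.column_stack([np.ones(len(time)), gompertz_data["age"], Z])
        theta = np.r_[
            model.intercept,
            model.age_coefficient,
            [model.coefficients[n] for n in panel.names],
            model.gamma,
        ]

        def neg_ll(params):
            return -gompertz_loglik(params[:-1], params[-1], X, time, event)

        # observed information by central finite differences
        p = len(theta)
        H = np.zeros((p, p))
        h = 1e-4 * np.maximum(np.abs(theta), 1.0)
        for i in range(p):
            for j in range(i, p):
                ei = np.eye(p)[i] * h[i]
                ej = np.eye(p)[j] * h[j]
                H[i, j] = H[j, i] = (
                    neg_ll(theta + ei + ej)
                    - neg_ll(theta + ei - ej)
                    - neg_ll(theta - ei + ej)
                    + neg_ll(theta - ei - ej)
                ) / (4 * h[i] * h[j])
        se = np.sqrt(np.diag(np.linalg.inv(H)))
        # generative coefficients mapped to the standardized scale of the fit:
        # z = (x - mean)/std, so beta_z = c * std and the intercept absorbs
        # sum(c * mean)
        gen = [0.3, -0.2, 0.15]
        stds = [gompertz_data[n].std() for n in panel.names]
        means = [gompertz_data[n].mean() for n in panel.names]
        truth = np.r_[
            -9.5 + sum(c * m for c, m in zip(gen, means)),
            0.09,
            [c * s for c, s in zip(gen, stds)],
            0.08,
        ]
        for i in range(p):
            assert abs(theta[i] - truth[i]) < 3 * se[i], f"param {i}"

    def test_no_events_rejected(self):
        table = pd.DataFrame(
            {"age": [50.0, 60.0, 55.0], "m1": [0.1, 0.2, -0.1],
             "follow_up_years": [27.0] * 3, "death": [0, 0, 0]}
        )
        with pytest.raises(ValueError, match="events"):
            fit_phenoage(table, small_panel(1))


def zero_weight_model(panel):
    return PhenoAgeModel(
        biomarkers=list(panel.names),
        coefficients={n: 0.0 for n in panel.names},
        intercept=-9.5,
        age_coefficient=0.09,
        gamma=0.08,
        standardize_center={n: 0.0 for n in panel.names},
        standardize_scale={n: 1.0 for n in panel.names},
        penalty_mix=0.5,
        penalty_strength=0.0,
        horizon=10.0,
        age_scale_constants=(-9.5, 0.09, 0.08),
    )


class TestScore:
    def test_zero_biomarker_weights_return_chronological_age(self):
        panel = small_panel(3)
        model = zero_weight_model(panel)
        rng = np.random.default_rng(2)
        target = pd.DataFrame({"age": rng.uniform(35, 75, 40)})
        for n in panel.names:
            target[n] = rng.normal(0, 5, 40)
        got = score_phenoage(model, target)
        np.testing.assert_allclose(got, target["age"], rtol=0, atol=1e-10)

    def test_strictly_monotone_in_linear_predictor(self):
        panel = small_panel(1)
        model = zero_weight_model(panel)
        model.coefficients["m1"] = 0.5
        target = pd.DataFrame({"age": [60.0, 60.0], "m1": [0.0, 1.0]})
        got = score_phenoage(model, target)
        assert got.iloc[1] > got.iloc[0]

    def test_matches_bisection_inversion_oracle(self, gompertz_data):
        panel = small_panel(3)
        model = fit_phenoage(gompertz_data, panel, penalty_strength=1e-3)
        target = gompertz_data.head(25)
        risk = mortality_risk(model, target).to_numpy()
        a0, a1, g = model.age_scale_constants

        def age_only_risk(a):
            return -np.expm1(-np.exp(a0 + a1 * a) * np.expm1(g * model.horizon) / g)

        got = score_phenoage(model, target).to_numpy()
        for i in range(len(target)):
            lo, hi = -500.0, 500.0
            for _ in range(200):
                mid = 0.5 * (lo + hi)
                if age_only_risk(mid) < risk[i]:
                    lo = mid
                else:
                    hi = mid
            assert got[i] == pytest.approx(0.5 * (lo + hi), abs=1e-6)
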