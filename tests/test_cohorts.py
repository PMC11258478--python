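"""Generator contracts: determinism, noiseless limits, marginal calibration."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from sleepbioage.cohorts import (
    generate_genotypes,
    generate_reference_cohort,
    generate_target_cohort,
    generative_mediation_truth,
    inject_missingness,
)
from sleepbioage.config import SyntheticConfig


def _noise_free(config: SyntheticConfig) -> SyntheticConfig:
    zero = {name: 0.0 for name in config.panel.names}
    return dataclasses.replace(config, biomarker_noise_sd=zero)


class TestReferenceCohort:
    def test_noiseless_limit_biomarkers_equal_linear_age_means(self):
        cfg = _noise_free(SyntheticConfig(n_reference=200, seed=3))
        table = generate_reference_cohort(cfg)
        for name in cfg.panel.names:
            expected = cfg.biomarker_means_at_50[name] + cfg.biomarker_age_slopes[name] * (
                table["age"] - 50.0
            )
            np.testing.assert_allclose(table[name], expected, rtol=0, atol=1e-12)

    def test_same_seed_gives_identical_tables(self):
        cfg = SyntheticConfig(n_reference=300, n_target=300, seed=11)
        a = generate_reference_cohort(cfg)
        b = generate_reference_cohort(cfg)
        assert a.to_csv() == b.to_csv()

    def test_follow_up_nonnegative_and_censored(self):
        cfg = SyntheticConfig(n_reference=2000, seed=5)
        t = generate_reference_cohort(cfg)
        assert (t["follow_up_years"] >= 0).all()
        assert (t["follow_up_years"] <= cfg.censoring_horizon).all()
        assert set(t["death"].unique()) <= {0, 1}
        # censored participants sit exactly at the administrative horizon
        assert (t.loc[t["death"] == 0, "follow_up_years"] == cfg.censoring_horizon).all()

    def test_age_slope_recovery_within_3_se(self):
        cfg = SyntheticConfig(n_reference=10_000, seed=17)
        t = generate_reference_cohort(cfg)
        age = t["age"].to_numpy()
        X = np.column_stack([np.ones_like(age), age])
        XtX_inv = np.linalg.inv(X.T @ X)
        for name in cfg.panel.names:
            y = t[name].to_numpy()
            beta = XtX_inv @ X.T @ y
            resid = y - X @ beta
            se = np.sqrt(XtX_inv[1, 1] * resid @ resid / (len(y) - 2))
            assert abs(beta[1] - cfg.biomarker_age_slopes[name]) < 3 * se, name


class TestTargetCohort:
    def test_zero_curvature_breaks_sleep_biomarker_link(self):
        """Null simulation: slope of biomarker on (hours-7)^2 should be
        insignificant at alpha=0.05 in at least 94 of 100 replicates."""
        from scipy import stats

        hits = 0
        for rep in range(100):
            cfg = SyntheticConfig(
                n_target=400, seed=1000 + rep, sleep_effect_curvature=0.0
            )
            t = generate_target_cohort(cfg)
            q = (t["sleep_hours"] - 7.0) ** 2
            res = stats.linregress(q, t["glucose"])
            hits += res.pvalue >= 0.05
        assert hits >= 94

    def test_full_cysc_routing_is_exact(self):
        """With mediated_fraction_cysc = 1, the sleep shift equals the
        cystatin-C deviation times its loading, analyte by analyte."""
        base = SyntheticConfig(
            n_target=500, seed=9, sleep_effect_curvature=0.0,
            mediated_fraction_cysc=1.0, mediated_fraction_ggt=0.0,
        )
        routed = dataclasses.replace(base, sleep_effect_curvature=0.08)
        t0 = generate_target_cohort(base)
        t1 = generate_target_cohort(routed)
        cysc_dev = t1["cysc"] - (base.cysc_mean + base.cysc_age_slope * (t1["age"] - 50.0))
        for name, sign in zip(base.panel.names, base.panel.risk_signs):
            loading = (
                sign * base.biomarker_noise_sd[name] * 0.08 / base.cysc_signal_per_h2
            )
            np.testing.assert_allclose(
                t1[name] - t0[name], loading * cysc_dev, rtol=0, atol=1e-9
            )

    def test_u_shape_burden_exceeds_reference_at_extremes(self):
        cfg = SyntheticConfig(n_target=20_000, seed=21, sleep_effect_curvature=0.08)
        t = generate_target_cohort(cfg)
        burden = np.zeros(len(t))
        for name, sign in zip(cfg.panel.names, cfg.panel.risk_signs):
            burden += sign * t[name] / cfg.biomarker_noise_sd[name]
        short = burden[np.isclose(t["sleep_hours"], 5.0)].mean()
        long = burden[np.isclose(t["sleep_hours"], 9.0)].mean()
        ref = burden[np.isclose(t["sleep_hours"], 7.0)].mean()
        assert short > ref and long > ref

    def test_sleep_hours_span_and_grid(self, target_cohort):
        hours = target_cohort["sleep_hours"]
        assert hours.min() <= 5.0 and hours.max() >= 9.0
        np.testing.assert_allclose(hours * 2, np.round(hours * 2))

    def test_determinism(self):
        cfg = SyntheticConfig(n_target=300, seed=42)
        assert generate_target_cohort(cfg).to_csv() == generate_target_cohort(cfg).to_csv()

    def test_generative_truth_reports_configured_fractions(self):
        cfg = SyntheticConfig(mediated_fraction_cysc=0.4, mediated_fraction_ggt=0.1)
        truth = generative_mediation_truth(cfg)
        assert truth["proportion_mediated_cysc"] == 0.4
        assert truth["proportion_mediated_ggt"] == 0.1
        assert truth["proportion_direct"] == pytest.approx(0.5)


class TestGenotypes:
    def test_no_missingness_when_rate_zero(self):
        cfg = SyntheticConfig(n_target=100, snp_count=20, missing_rate=0.0, seed=2)
        dosage, _ = generate_genotypes(cfg)
        assert not dosage.isna().any().any()
        assert set(np.unique(dosage.to_numpy())) <= {0.0, 1.0, 2.0}

    def test_zero_frequency_snp_is_all_reference_allele(self):
        cfg = SyntheticConfig(n_target=200, snp_count=3, missing_rate=0.0, seed=2)
        dosage, _ = generate_genotypes(cfg, allele_freqs=np.array([0.0, 0.5, 1.0]))
        assert (dosage.iloc[:, 0] == 0).all()
        assert (dosage.iloc[:, 2] == 2).all()

    def test_weight_table_matches_sleep_duration_instrument_size(self):
        cfg = SyntheticConfig(n_target=50, snp_count=112, seed=2)
        _, weights = generate_genotypes(cfg)
        assert len(weights) == 112
        assert list(weights.columns) == ["snp_id", "effect_allele", "effect_size"]

    def test_missing_rate_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(missing_rate=1.5)

    def test_determinism(self):
        cfg = SyntheticConfig(n_target=80, snp_count=10, seed=6)
        d1, w1 = generate_genotypes(cfg)
        d2, w2 = generate_genotypes(cfg)
        pd.testing.assert_frame_equal(d1, d2)
        pd.testing.assert_frame_equal(w1, w2)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_reference": 1},
            {"age_range": (70.0, 40.0)},
            {"mediated_fraction_cysc": 1.2},
            {"mediated_fraction_cysc": 0.7, "mediated_fraction_ggt": 0.5},
            {"sleep_effect_curvature": float("nan")},
            {"snp_count": 0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticConfig(**kwargs)

    def test_yaml_round_trip(self, tmp_path):
        cfg = SyntheticConfig(n_target=123, seed=77, sleep_effect_curvature=0.03)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(str(path))
        back = SyntheticConfig.from_yaml(str(path))
        assert back.to_dict() == cfg.to_dict()


def test_inject_missingness_counts_are_exact():
    cfg = SyntheticConfig(n_target=500, seed=13)
    t = generate_target_cohort(cfg)
    injected, counts = inject_missingness(t, {"cysc": 7, "bmi": 11, "sleep_hours": 3}, seed=1)
    assert injected["cysc"].isna().sum() == 7
    assert injected["bmi"].isna().sum() == 11
    assert injected["sleep_hours"].isna().sum() == 3
    assert counts == {"cysc": 7, "bmi": 11, "sleep_hours": 3}
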