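"""Synthetic cohort, genotype, and weight-table generators.

Two cohorts are produced with the statistical structure the analysis
chain assumes:

* a *reference* cohort with mortality follow-up, used to train the
  predicted-age metrics (a synthetic stand-in for a survey cohort with
  linked death records) -- biomarkers drift linearly with age plus
  Gaussian noise, and death times follow a Gompertz hazard whose
  log-hazard is linear in age and in a risk-signed standardized
  combination of the biomarkers;
* a *target* cohort carrying habitual sleep duration, sleep behaviours,
  covariates, and the two mediators (cystatin C, GGT). Sleep shifts every
  biomarker in its risk direction by ``curvature * (hours - 7)^2`` noise-SD
  units, and a configurable fraction of that shift is routed through each
  mediator, so the generative proportion mediated is known exactly.

All generators are deterministic given ``config.seed``; each draws from
its own derived stream so cohorts and genotypes do not perturb each
other's randomness.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SLEEP_CATEGORY_GRIDS, SLEEP_CATEGORY_PROBS, SyntheticConfig

# stream ids fanned out from the base seed
_REFERENCE_STREAM = 11
_TARGET_STREAM = 23
_GENOTYPE_STREAM = 37

COVARIATE_COLUMNS = [
    "age",
    "sex",
    "bmi",
    "smoking",
    "drinking",
    "phys_activity",
    "education",
    "tdi",
    "diet_score",
    "health_rating",
    "disease_history",
    "family_history",
    "medication",
    "sleep_disorder",
    "depression",
    "shift_work",
]

SLEEP_BEHAVIOR_COLUMNS = [
    "chronotype_morning",
    "no_insomnia",
    "no_daytime_sleepiness",
    "no_snoring",
]


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def _draw_biomarkers(
    config: SyntheticConfig, age: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Linear-in-age means plus correlated Gaussian noise.

    A shared physiological-burden factor loads on every analyte in its
    risk direction (scaled by the analyte's noise SD), so the panel shows
    the modest positive risk-direction correlation real blood panels do.
    """
    burden = rng.normal(0.0, 1.0, size=age.size)
    cols = {}
    for name, sign in zip(config.panel.names, config.panel.risk_signs):
        mean = config.biomarker_means_at_50[name] + config.biomarker_age_slopes[name] * (
            age - 50.0
        )
        sd = config.biomarker_noise_sd[name]
        noise = rng.normal(0.0, 1.0, size=age.size)
        cols[name] = mean + sd * (noise + sign * config.burden_loading * burden)
    return pd.DataFrame(cols)


def _draw_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Adjustment covariates, drawn independently of exposure and outcome."""
    sex = rng.binomial(1, 0.54, n)  # 1 = female
    return pd.DataFrame(
        {
            "sex": sex,
            "bmi": rng.normal(27.3, 4.5, n),
            "smoking": rng.binomial(1, 0.45, n),
            "drinking": rng.binomial(1, 0.92, n),
            "phys_activity": rng.choice(3, size=n, p=[0.20, 0.45, 0.35]),
            "education": rng.binomial(1, 0.33, n),
            "tdi": rng.normal(-1.3, 3.0, n),
            "diet_score": rng.binomial(7, 0.55, n),
            "health_rating": rng.choice(4, size=n, p=[0.16, 0.58, 0.21, 0.05]),
            "disease_history": rng.binomial(1, 0.33, n),
            "family_history": rng.binomial(1, 0.55, n),
            "medication": rng.binomial(1, 0.13, n),
            "sleep_disorder": rng.binomial(1, 0.02, n),
            "depression": rng.binomial(1, 0.06, n),
            "shift_work": rng.binomial(1, 0.08, n),
            "pregnant": sex * rng.binomial(1, 0.005, n),
            "energy_kcal": rng.normal(2100.0, 450.0, n),
        }
    )


def _mediator_age_mean(config: SyntheticConfig, age: np.ndarray, which: str) -> np.ndarray:
    if which == "cysc":
        return config.cysc_mean + config.cysc_age_slope * (age - 50.0)
    return config.ggt_mean + config.ggt_age_slope * (age - 50.0)


def generate_reference_cohort(config: SyntheticConfig) -> pd.DataFrame:
    """Training cohort with Gompertz mortality follow-up.

    The log hazard at follow-up time ``t`` for a participant with baseline
    age ``a`` and biomarker vector ``x`` is

        log h(t) = log_rate + shape * (a + t) + w * sum_j dir_j * z_j

    where ``z_j`` is biomarker ``j``'s deviation from its age-expected mean
    in noise-SD units and ``dir_j`` its risk sign. Death times are drawn by
    inverse transform from the implied Gompertz survival function and
    administratively censored at ``config.censoring_horizon`` years.
    """
    config.validate()
    rng = _rng(config, _REFERENCE_STREAM)
    n = config.n_reference
    age = rng.uniform(config.age_range[0], config.age_range[1], n)
    bio = _draw_biomarkers(config, age, rng)

    # risk-signed standardized biomarker burden drives the hazard
    burden = np.zeros(n)
    for name, sign in zip(config.panel.names, config.panel.risk_signs):
        sd = config.biomarker_noise_sd[name]
        if sd > 0:
            mean = config.biomarker_means_at_50[name] + config.biomarker_age_slopes[
                name
            ] * (age - 50.0)
            burden += sign * (bio[name].to_numpy() - mean) / sd

    shape = config.mortality_gompertz_shape
    lp = config.mortality_log_rate + shape * age + config.mortality_biomarker_weight * burden
    u = rng.uniform(size=n)
    # S(t) = exp(-(e^lp/shape)(e^{shape t}-1))  =>  t = log(1 - shape*log(u)*e^{-lp})/shape
    t_death = np.log1p(-shape * np.log(u) * np.exp(-lp)) / shape
    death = (t_death <= config.censoring_horizon).astype(int)
    follow_up = np.minimum(t_death, config.censoring_horizon)

    cov = _draw_covariates(n, rng)
    table = pd.DataFrame(
        {
            "participant_id": [f"R{i:06d}" for i in range(n)],
            "age": age,
        }
    )
    table = pd.concat([table, cov, bio], axis=1)
    table["cysc"] = _mediator_age_mean(config, age, "cysc") + rng.normal(
        0.0, config.cysc_noise_sd, n
    )
    table["ggt"] = _mediator_age_mean(config, age, "ggt") + rng.normal(
        0.0, config.ggt_noise_sd, n
    )
    table["follow_up_years"] = follow_up
    table["death"] = death
    return table


def _draw_sleep_hours(config: SyntheticConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    cats = list(SLEEP_CATEGORY_PROBS)
    probs = np.array([SLEEP_CATEGORY_PROBS[c] for c in cats])
    probs = probs / probs.sum()
    which = rng.choice(len(cats), size=n, p=probs)
    hours = np.empty(n)
    for k, cat in enumerate(cats):
        grid = np.asarray(SLEEP_CATEGORY_GRIDS[cat])
        idx = which == k
        hours[idx] = rng.choice(grid, size=int(idx.sum()))
    if config.round_sleep_to_integers:
        hours = np.floor(hours + 0.5)
    return hours


def generate_target_cohort(config: SyntheticConfig) -> pd.DataFrame:
    """Analysis cohort with sleep exposures, mediators, and covariates.

    The sleep signal is ``q = (hours - 7)^2``. Each analyte ``j`` is shifted
    by ``dir_j * sd_j * curvature * q`` in total; fractions
    ``mediated_fraction_cysc`` and ``mediated_fraction_ggt`` of that shift
    are carried by the mediator deviations (which include the mediators'
    own noise, so the mediation structural equations hold exactly), and
    the remainder is applied directly.
    """
    config.validate()
    rng = _rng(config, _TARGET_STREAM)
    n = config.n_target
    age = rng.uniform(config.age_range[0], config.age_range[1], n)
    bio = _draw_biomarkers(config, age, rng)
    hours = _draw_sleep_hours(config, n, rng)
    q = (hours - 7.0) ** 2

    m_c, m_g = config.mediated_fraction_cysc, config.mediated_fraction_ggt
    if m_c > 0 and config.cysc_signal_per_h2 == 0:
        raise ValueError("mediated_fraction_cysc > 0 requires cysc_signal_per_h2 != 0")
    if m_g > 0 and config.ggt_signal_per_h2 == 0:
        raise ValueError("mediated_fraction_ggt > 0 requires ggt_signal_per_h2 != 0")

    cysc_dev = config.cysc_signal_per_h2 * q + rng.normal(0.0, config.cysc_noise_sd, n)
    ggt_dev = config.ggt_signal_per_h2 * q + rng.normal(0.0, config.ggt_noise_sd, n)
    cysc = _mediator_age_mean(config, age, "cysc") + cysc_dev
    ggt = _mediator_age_mean(config, age, "ggt") + ggt_dev

    c = config.sleep_effect_curvature
    for name, sign in zip(config.panel.names, config.panel.risk_signs):
        total_per_q = sign * config.biomarker_noise_sd[name] * c
        direct = (1.0 - m_c - m_g) * total_per_q * q
        via_c = (m_c * total_per_q / config.cysc_signal_per_h2) * cysc_dev if m_c > 0 else 0.0
        via_g = (m_g * total_per_q / config.ggt_signal_per_h2) * ggt_dev if m_g > 0 else 0.0
        bio[name] = bio[name] + direct + via_c + via_g

    cov = _draw_covariates(n, rng)
    behaviors = pd.DataFrame(
        {
            "chronotype_morning": rng.binomial(1, 0.56, n),
            "no_insomnia": rng.binomial(1, 0.60, n),
            "no_daytime_sleepiness": rng.binomial(1, 0.75, n),
            "no_snoring": rng.binomial(1, 0.37, n),
        }
    )
    table = pd.DataFrame(
        {
            "participant_id": [f"T{i:06d}" for i in range(n)],
            "age": age,
            "sleep_hours": hours,
        }
    )
    table = pd.concat([table, behaviors, cov, bio], axis=1)
    table["cysc"] = cysc
    table["ggt"] = ggt
    return table


def generate_genotypes(
    config: SyntheticConfig,
    participant_ids: list[str] | None = None,
    allele_freqs: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Biallelic dosage matrix plus a per-SNP weight table.

    Dosages are Binomial(2, f_i) counts of the effect allele with per-SNP
    frequencies f_i ~ U(0.05, 0.95); entries are set missing (NaN)
    independently at ``missing_rate``. Weights are positive per-allele
    effect magnitudes.
    """
    config.validate()
    rng = _rng(config, _GENOTYPE_STREAM)
    if participant_ids is None:
        participant_ids = [f"T{i:06d}" for i in range(config.n_target)]
    n, m = len(participant_ids), config.snp_count
    if allele_freqs is None:
        freqs = rng.uniform(0.05, 0.95, m)
    else:
        freqs = np.asarray(allele_freqs, dtype=float)
        if freqs.shape != (m,) or (freqs < 0).any() or (freqs > 1).any():
            raise ValueError("allele_freqs must be snp_count probabilities in [0, 1]")
    dosage = rng.binomial(2, freqs, size=(n, m)).astype(float)
    if config.missing_rate > 0:
        mask = rng.uniform(size=(n, m)) < config.missing_rate
        dosage[mask] = np.nan
    snp_ids = [f"snp{i:04d}" for i in range(m)]
    dosage_df = pd.DataFrame(dosage, index=pd.Index(participant_ids, name="participant_id"),
                             columns=snp_ids)
    weights = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "effect_allele": rng.choice(list("ACGT"), size=m),
            "effect_size": rng.uniform(0.01, 0.10, m),
        }
    )
    return dosage_df, weights


def inject_missingness(
    table: pd.DataFrame, counts: dict[str, int], seed: int
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Blank out known numbers of rows per column, on disjoint row sets.

    Returns the modified copy and the injected counts (for bookkeeping
    checks of the exclusion ledger). Disjointness makes the per-criterion
    exclusion counts equal the injected counts regardless of the order in
    which exclusion criteria are applied.
    """
    rng = np.random.default_rng(seed)
    total = sum(counts.values())
    if total > len(table):
        raise ValueError("cannot inject more missing rows than the table has")
    rows = rng.choice(len(table), size=total, replace=False)
    out = table.copy()
    start = 0
    for col, k in counts.items():
        out.loc[out.index[rows[start : start + k]], col] = np.nan
        start += k
    return out, dict(counts)


def generative_mediation_truth(config: SyntheticConfig) -> dict[str, float]:
    """Exact mediated proportions implied by the generative construction.

    Every analyte's sleep shift is split ``(1 - m_c - m_g) : m_c : m_g``
    between the direct path and the two mediator paths, so any linear
    functional of the biomarker vector inherits the same split.
    """
    return {
        "proportion_mediated_cysc": config.mediated_fraction_cysc,
        "proportion_mediated_ggt": config.mediated_fraction_ggt,
        "proportion_direct": 1.0
        - config.mediated_fraction_cysc
        - config.mediated_fraction_ggt,
    }
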