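"""PhenoAge: mortality-calibrated biological age.

A Gompertz proportional-hazards model is fitted to the reference cohort's
follow-up, with log hazard

    log h(t) = b0 + b_age * CA + sum_j b_j * z_j + gamma * t,

where z_j are standardized biomarkers and t is time since baseline. The
biomarker coefficients carry an elastic-net penalty (chronological age is
never penalized). Scoring converts a participant's linear predictor into
the probability of death within a fixed horizon H,

    M = 1 - exp(-exp(xb) * (e^{gamma H} - 1) / gamma),

then maps that risk back to the age scale by inverting the same
horizon-risk curve of an age-only Gompertz model fitted to the same
reference. A participant whose biomarkers contribute nothing therefore
scores exactly their chronological age, and PhenoAge is strictly
increasing in the linear predictor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from ..panel import BiomarkerPanel

log = logging.getLogger(__name__)

_SMOOTH_L1_EPS = 1e-8


@dataclass
class PhenoAgeModel:
    biomarkers: list[str]
    coefficients: dict[str, float]  # per standardized biomarker
    intercept: float
    age_coefficient: float
    gamma: float
    standardize_center: dict[str, float]
    standardize_scale: dict[str, float]
    penalty_mix: float
    penalty_strength: float
    horizon: float
    # (intercept, age slope, gamma) of the age-only Gompertz model
    age_scale_constants: tuple[float, float, float] = field(default=(0.0, 0.0, 0.0))
    risk_epsilon: float = 1e-10

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["age_scale_constants"] = list(self.age_scale_constants)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhenoAgeModel":
        d = dict(d)
        d["age_scale_constants"] = tuple(d["age_scale_constants"])
        return cls(**d)


def gompertz_loglik(beta: np.ndarray, gamma: float, X: np.ndarray,
                    time: np.ndarray, event: np.ndarray) -> float:
    """Log-likelihood of the Gompertz PH model (beta includes intercept)."""
    xb = X @ beta
    egt = np.expm1(gamma * time)
    return float(np.sum(event * (xb + gamma * time) - np.exp(xb) * egt / gamma))


def _neg_loglik_and_grad(params, X, time, event, pen_idx, strength, mix):
    n = X.shape[0]
    beta, loggamma = params[:-1], params[-1]
    gamma = np.exp(loggamma)
    xb = X @ beta
    exb = np.exp(xb)
    egt = np.expm1(gamma * time)
    ll = np.sum(event * (xb + gamma * time) - exb * egt / gamma)

    gbeta = X.T @ (event - exb * egt / gamma)
    # d/dgamma of (e^{gamma t}-1)/gamma
    dfrac = (time * np.exp(gamma * time) * gamma - egt) / gamma**2
    ggamma = np.sum(event * time - exb * dfrac) * gamma  # chain rule for log gamma

    b = beta[pen_idx]
    smooth_abs = np.sqrt(b**2 + _SMOOTH_L1_EPS)
    pen = strength * (mix * np.sum(smooth_abs) + 0.5 * (1 - mix) * np.sum(b**2))
    gpen = np.zeros_like(beta)
    gpen[pen_idx] = strength * (mix * b / smooth_abs + (1 - mix) * b)

    f = -ll / n + pen
    g = np.concatenate([-gbeta / n + gpen, [-ggamma / n]])
    return f, g


def _fit_gompertz(X, time, event, pen_idx, strength, mix, gamma0=0.08):
    p = X.shape[1]
    x0 = np.zeros(p + 1)
    x0[0] = np.log(max(np.mean(event), 1e-3) / np.mean(time))  # crude rate start
    x0[-1] = np.log(gamma0)
    res = optimize.minimize(
        _neg_loglik_and_grad,
        x0,
        args=(X, time, event, pen_idx, strength, mix),
        jac=True,
        method="L-BFGS-B",
        bounds=[(None, None)] * p + [(np.log(1e-4), np.log(1.0))],
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
    )
    grad_norm = float(np.max(np.abs(res.jac)))
    if not res.success and grad_norm > 1e-4:
        raise RuntimeError(
            f"Gompertz fit did not converge: {res.message} (max|grad| = {grad_norm:.3g})"
        )
    return res.x[:-1], float(np.exp(res.x[-1]))


def fit_phenoage(
    reference: pd.DataFrame,
    panel: BiomarkerPanel,
    penalty_mix: float = 0.5,
    penalty_strength: float = 1e-3,
    horizon: float = 10.0,
    age_column: str = "age",
    time_column: str = "follow_up_years",
    event_column: str = "death",
) -> PhenoAgeModel:
    """Fit the elastic-net Gompertz model plus the age-only calibration model.

    Biomarkers are standardized internally (center/scale stored on the
    model) so the elastic-net penalty treats them symmetrically;
    ``penalty_mix`` is the L1 share of the penalty and
    ``penalty_strength`` its overall weight (per-observation scale).
    """
    time = reference[time_column].to_numpy(dtype=float)
    event = reference[event_column].to_numpy(dtype=float)
    if (time < 0).any():
        raise ValueError("negative follow-up time")
    if event.sum() < 1:
        raise ValueError("reference cohort contains no death events")
    age = reference[age_column].to_numpy(dtype=float)

    center, scale = {}, {}
    cols = [np.ones_like(age), age]
    for name in panel.names:
        x = reference[name].to_numpy(dtype=float)
        c, s = float(np.mean(x)), float(np.std(x))
        if s == 0:
            raise ValueError(f"biomarker {name!r} has zero variance")
        center[name], scale[name] = c, s
        cols.append((x - c) / s)
    X = np.column_stack(cols)
    pen_idx = np.arange(2, X.shape[1])  # penalize biomarkers only

    beta, gamma = _fit_gompertz(X, time, event, pen_idx, penalty_strength, penalty_mix)
    # age-only model for the risk -> age conversion
    X0 = np.column_stack([np.ones_like(age), age])
    beta0, gamma0 = _fit_gompertz(X0, time, event, np.array([], dtype=int), 0.0, 0.0)

    return PhenoAgeModel(
        biomarkers=list(panel.names),
        coefficients={n: float(b) for n, b in zip(panel.names, beta[2:])},
        intercept=float(beta[0]),
        age_coefficient=float(beta[1]),
        gamma=gamma,
        standardize_center=center,
        standardize_scale=scale,
        penalty_mix=penalty_mix,
        penalty_strength=penalty_strength,
        horizon=horizon,
        age_scale_constants=(float(beta0[0]), float(beta0[1]), gamma0),
    )


def mortality_risk(model: PhenoAgeModel, target: pd.DataFrame,
                   age_column: str = "age") -> pd.Series:
    """Probability of death within ``model.horizon`` years."""
    xb = model.intercept + model.age_coefficient * target[age_column].to_numpy(dtype=float)
    for name in model.biomarkers:
        z = (target[name].to_numpy(dtype=float) - model.standardize_center[name]) / (
            model.standardize_scale[name]
        )
        xb = xb + model.coefficients[name] * z
    risk = -np.expm1(-np.exp(xb) * np.expm1(model.gamma * model.horizon) / model.gamma)
    return pd.Series(risk, index=target.index, name="mortality_risk")


def score_phenoage(model: PhenoAgeModel, target: pd.DataFrame,
                   age_column: str = "age") -> pd.Series:
    """Invert the age-only horizon-risk curve at each participant's risk.

    The inversion is closed-form: with age-only constants (a0, a1, g),
    risk M satisfies log(-log(1 - M)) = a0 + a1 * A + log((e^{gH}-1)/g),
    so A = (log(-log(1 - M)) - a0 - log((e^{gH}-1)/g)) / a1.
    """
    a0, a1, g = model.age_scale_constants
    risk = mortality_risk(model, target, age_column=age_column).to_numpy()
    eps = model.risk_epsilon
    n_clamped = int(np.sum((risk <= eps) | (risk >= 1 - eps)))
    if n_clamped:
        log.warning("clamping %d mortality risks to [%g, %g]", n_clamped, eps, 1 - eps)
    risk = np.clip(risk, eps, 1 - eps)
    offset = np.log(np.expm1(g * model.horizon) / g)
    phenoage = (np.log(-np.log1p(-risk)) - a0 - offset) / a1
    return pd.Series(phenoage, index=target.index, name="phenoage")
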