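"""Product-of-coefficients mediation with nonparametric bootstrap.

Two linear models on standardized variables:

    mediator ~ exposure + covariates          (a = exposure coefficient)
    outcome  ~ exposure + mediator + covariates
                                              (c' = direct, b = mediator)

The average causal mediation effect (ACME, indirect effect) is a*b, the
average direct effect (ADE) is c', and in this linear no-interaction
setting the total effect is exactly their sum. Percentile confidence
intervals come from a participant-level nonparametric bootstrap;
proportion mediated is ACME / total x 100.

Sleep duration affects the metrics symmetrically around 7 h/day, so the
default exposure contrast is the squared deviation (hours - 7)^2 -- the
U-shape's own scale; a per-hour linear contrast and arbitrary exposure
columns are also supported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import _covariate_design
from .exposure import CovariateSpec

log = logging.getLogger(__name__)

TOTAL_EFFECT_TOLERANCE = 1e-10


@dataclass
class MediationResult:
    outcome: str
    mediator: str
    contrast: str
    total: float
    direct: float  # ADE
    indirect: float  # ACME
    proportion_mediated: float  # percent; NaN when total ~ 0
    ci_total: tuple[float, float]
    ci_direct: tuple[float, float]
    ci_indirect: tuple[float, float]
    ci_proportion: tuple[float, float]
    p_total: float
    p_direct: float
    p_indirect: float
    n: int
    n_boot: int
    seed: int


def _exposure_vector(table: pd.DataFrame, contrast: str,
                     hours_column: str = "sleep_hours") -> np.ndarray:
    if contrast == "hours":
        return table[hours_column].to_numpy(dtype=float)
    if contrast == "squared_deviation":
        return (table[hours_column].to_numpy(dtype=float) - 7.0) ** 2
    if contrast in table.columns:
        return table[contrast].to_numpy(dtype=float)
    raise ValueError(f"unknown exposure contrast {contrast!r}")


def _standardize(v: np.ndarray) -> np.ndarray:
    s = v.std()
    if s == 0:
        raise ValueError("cannot standardize a constant variable")
    return (v - v.mean()) / s


def _paths(Xm: np.ndarray, Xy: np.ndarray, m: np.ndarray, y: np.ndarray):
    """(a, b, c') from the two least-squares fits."""
    am = np.linalg.lstsq(Xm, m, rcond=None)[0]
    ay = np.linalg.lstsq(Xy, y, rcond=None)[0]
    return am[1], ay[2], ay[1]


def _boot_p(draws: np.ndarray) -> float:
    """Two-sided bootstrap p-value from the sign distribution."""
    frac = min(np.mean(draws <= 0.0), np.mean(draws >= 0.0))
    return float(min(1.0, 2.0 * frac))


def fit_mediation(
    table: pd.DataFrame,
    outcome: str,
    mediator: str,
    spec: CovariateSpec | None = None,
    contrast: str = "squared_deviation",
    n_boot: int = 1000,
    seed: int = 0,
    hours_column: str = "sleep_hours",
) -> MediationResult:
    """Estimate ACME, ADE, total effect, and proportion mediated."""
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    spec = spec or CovariateSpec()
    e = _standardize(_exposure_vector(table, contrast, hours_column))
    m = _standardize(table[mediator].to_numpy(dtype=float))
    y = _standardize(table[outcome].to_numpy(dtype=float))
    C = _covariate_design(table, spec).to_numpy(dtype=float)
    n = len(y)
    ones = np.ones((n, 1))
    Xm = np.column_stack([ones, e[:, None], C])
    Xy = np.column_stack([ones, e[:, None], m[:, None], C])

    a, b, cprime = _paths(Xm, Xy, m, y)
    indirect = a * b
    total = cprime + indirect
    if abs(total) < TOTAL_EFFECT_TOLERANCE:
        log.warning("total effect ~ 0 (%.3g); proportion mediated undefined", total)
        proportion = float("nan")
    else:
        proportion = 100.0 * indirect / total

    rng = np.random.default_rng(seed)
    draws = np.empty((n_boot, 3))
    for r in range(n_boot):
        idx = rng.integers(0, n, size=n)
        ar, br, cr = _paths(Xm[idx], Xy[idx], m[idx], y[idx])
        draws[r] = (ar * br + cr, cr, ar * br)
    tot_d, dir_d, ind_d = draws[:, 0], draws[:, 1], draws[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        prop_d = np.where(np.abs(tot_d) < TOTAL_EFFECT_TOLERANCE, np.nan,
                          100.0 * ind_d / tot_d)

    def ci(v):
        v = v[np.isfinite(v)]
        if len(v) == 0:
            return (float("nan"), float("nan"))
        return (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))

    return MediationResult(
        outcome=outcome,
        mediator=mediator,
        contrast=contrast,
        total=float(total),
        direct=float(cprime),
        indirect=float(indirect),
        proportion_mediated=float(proportion),
        ci_total=ci(tot_d),
        ci_direct=ci(dir_d),
        ci_indirect=ci(ind_d),
        ci_proportion=ci(prop_d),
        p_total=_boot_p(tot_d),
        p_direct=_boot_p(dir_d),
        p_indirect=_boot_p(ind_d),
        n=n,
        n_boot=n_boot,
        seed=seed,
    )


def summarize_mediators(results: list[MediationResult]) -> pd.DataFrame:
    """Metric x mediator table of proportions mediated with CIs.

    Expects one result per (outcome, mediator) pair; undefined
    proportions render as NA with a footnote flag.
    """
    rows = []
    for r in results:
        undefined = not np.isfinite(r.proportion_mediated)
        rows.append(
            {
                "outcome": r.outcome,
                "mediator": r.mediator,
                "proportion_mediated_pct": (
                    float("nan") if undefined else round(r.proportion_mediated, 1)
                ),
                "ci_low_pct": round(r.ci_proportion[0], 1),
                "ci_high_pct": round(r.ci_proportion[1], 1),
                "indirect": r.indirect,
                "total": r.total,
                "p_indirect": r.p_indirect,
                "note": "total effect ~ 0; proportion undefined" if undefined else "",
            }
        )
    table = pd.DataFrame(rows)
    pairs = table[["outcome", "mediator"]].drop_duplicates()
    if len(pairs) != len(table):
        raise ValueError("duplicate (outcome, mediator) results supplied")
    return table
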