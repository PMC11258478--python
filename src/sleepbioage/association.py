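"""Covariate-adjusted models linking sleep duration to the age metrics.

Four model families, all ordinary least squares on the target cohort:

* categorical contrasts of the five duration categories against the
  7 h/day reference;
* a linear trend test in which each participant's category is replaced
  by the within-category median of observed hours and treated as
  continuous;
* restricted cubic spline (natural spline) dose-response with three
  knots at the 10th/50th/90th percentiles of hours, a 2-df Wald test for
  any association and a 1-df Wald test for nonlinearity, and a predicted
  curve anchored to zero at the reference duration;
* stratum-interaction tests (joint Wald test on category x stratum
  product terms) with per-stratum refits.

Wald tests use the large-sample chi-square reference. The pipeline's
significance flag applies a Bonferroni threshold of 0.05 / (number of
outcome families), 0.01 by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exposure import CovariateSpec, REFERENCE_CATEGORY, SLEEP_CATEGORIES

log = logging.getLogger(__name__)

Z95 = 1.959963984540054  # two-sided 95% normal quantile


def bonferroni_threshold(n_outcomes: int = 5, family_alpha: float = 0.05) -> float:
    return family_alpha / n_outcomes


@dataclass
class LinearModelResult:
    """Tidy coefficient table plus fit metadata for one OLS model."""

    outcome: str
    terms: pd.DataFrame  # term, beta, se, ci_low, ci_high, p
    n: int
    resid_var: float
    design: str
    extras: dict = field(default_factory=dict)

    def term(self, name: str) -> pd.Series:
        row = self.terms.loc[self.terms["term"] == name]
        if row.empty:
            raise KeyError(name)
        return row.iloc[0]


@dataclass
class RCSFit:
    """Restricted-cubic-spline dose-response fit."""

    outcome: str
    knots: tuple[float, ...]
    coefficients: np.ndarray  # (linear, nonlinear...) spline coefficients
    covariance: np.ndarray  # their covariance block
    reference_hours: float
    curve: pd.DataFrame  # hours, estimate, ci_low, ci_high
    p_overall: float
    p_nonlinear: float
    n: int


def _covariate_design(table: pd.DataFrame, spec: CovariateSpec) -> pd.DataFrame:
    """Dummy-coded covariate columns (reference levels dropped)."""
    parts = {}
    for col in spec.continuous:
        parts[col] = table[col].to_numpy(dtype=float)
    for col in spec.binary:
        parts[col] = table[col].to_numpy(dtype=float)
    for col, ref in spec.categorical.items():
        levels = sorted(pd.unique(table[col].dropna()))
        for lev in levels:
            if lev == ref:
                continue
            parts[f"{col}[{lev}]"] = (table[col] == lev).to_numpy(dtype=float)
    return pd.DataFrame(parts, index=table.index)


def _category_dummies(
    categories: pd.Series, reference: str = REFERENCE_CATEGORY
) -> pd.DataFrame:
    levels = [c for c in SLEEP_CATEGORIES if c != reference]
    return pd.DataFrame(
        {f"sleep[{lev}]": (categories == lev).astype(float) for lev in levels},
        index=categories.index,
    )


def _ols(y: np.ndarray, X: pd.DataFrame):
    X = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify a collinear column for the error message
        _, R = np.linalg.qr(X.to_numpy())
        bad = [X.columns[i] for i in range(X.shape[1]) if abs(R[i, i]) < 1e-8]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    return sm.OLS(y, X).fit()


def _tidy(res, outcome: str, design: str, extras: dict | None = None) -> LinearModelResult:
    terms = pd.DataFrame(
        {
            "term": res.params.index,
            "beta": res.params.to_numpy(),
            "se": res.bse.to_numpy(),
        }
    )
    terms["ci_low"] = terms["beta"] - Z95 * terms["se"]
    terms["ci_high"] = terms["beta"] + Z95 * terms["se"]
    # large-sample normal reference, matching the chi-square Wald convention
    terms["p"] = 2.0 * stats.norm.sf(np.abs(terms["beta"] / terms["se"]))
    return LinearModelResult(
        outcome=outcome,
        terms=terms.reset_index(drop=True),
        n=int(res.nobs),
        resid_var=float(res.scale),
        design=design,
        extras=extras or {},
    )


def fit_category_model(
    table: pd.DataFrame,
    outcome: str,
    spec: CovariateSpec | None = None,
    category_column: str = "sleep_category",
) -> LinearModelResult:
    """Per-category contrasts against the 7 h/day reference.

    The reference category is reported with beta exactly 0 and no
    interval, mirroring forest-plot convention.
    """
    spec = spec or CovariateSpec()
    y = table[outcome].to_numpy(dtype=float)
    if not np.isfinite(y).all():
        raise ValueError(f"outcome {outcome!r} contains non-finite values")
    X = pd.concat(
        [_category_dummies(table[category_column]), _covariate_design(table, spec)],
        axis=1,
    )
    res = _ols(y, X)
    tidy = _tidy(res, outcome, design="category + covariates")
    ref_row = pd.DataFrame(
        [
            {
                "term": f"sleep[{REFERENCE_CATEGORY}]",
                "beta": 0.0,
                "se": 0.0,
                "ci_low": 0.0,
                "ci_high": 0.0,
                "p": np.nan,
            }
        ]
    )
    tidy.terms = pd.concat([tidy.terms, ref_row], ignore_index=True)
    return tidy


def fit_trend_model(
    table: pd.DataFrame,
    outcome: str,
    spec: CovariateSpec | None = None,
    category_column: str = "sleep_category",
    hours_column: str = "sleep_hours",
) -> LinearModelResult:
    """Median-substitution linear trend across duration categories."""
    spec = spec or CovariateSpec()
    medians = table.groupby(category_column, observed=True)[hours_column].median()
    empty = [c for c in pd.unique(table[category_column].dropna()) if c not in medians.index]
    if empty or medians.isna().any():
        raise ValueError(f"categories without computable median hours: {empty}")
    trend = table[category_column].map(medians).astype(float)
    X = pd.concat(
        [trend.rename("sleep_trend").to_frame(), _covariate_design(table, spec)], axis=1
    )
    res = _ols(table[outcome].to_numpy(dtype=float), X)
    out = _tidy(res, outcome, design="median-substituted trend + covariates")
    out.extras["category_medians"] = {str(k): float(v) for k, v in medians.items()}
    return out


def rcs_basis(x: np.ndarray, knots: tuple[float, ...] | np.ndarray) -> np.ndarray:
    """Restricted (natural) cubic spline basis, truncated-power form.

    With k knots t_1 < ... < t_k the basis has k-1 columns: x itself plus,
    for j = 1..k-2,

        C_j(x) = [ (x-t_j)+^3
                   - (x-t_{k-1})+^3 (t_k-t_j)/(t_k-t_{k-1})
                   + (x-t_k)+^3 (t_{k-1}-t_j)/(t_k-t_{k-1}) ] / (t_k-t_1)^2,

    which is linear beyond the boundary knots. With 3 knots that is one
    linear and one nonlinear column.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    if not np.all(np.diff(t) > 0):
        raise ValueError(f"knots must be strictly increasing, got {t}")
    k = len(t)
    norm = (t[-1] - t[0]) ** 2

    def plus3(v):
        return np.maximum(v, 0.0) ** 3

    cols = [x]
    for j in range(k - 2):
        c = (
            plus3(x - t[j])
            - plus3(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
            + plus3(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2])
        ) / norm
        cols.append(c)
    return np.column_stack(cols)


def _distinct_quantile_knots(
    x: np.ndarray, quantiles: tuple[float, ...]
) -> tuple[float, ...]:
    """Quantile knots with a deterministic nearest-distinct fallback.

    Heavily tied integer hours can put two quantiles on the same value;
    in that case each colliding knot moves to the nearest distinct
    observed value (outward from the median), logged.
    """
    knots = [float(np.quantile(x, q)) for q in quantiles]
    if len(set(knots)) == len(knots):
        return tuple(knots)
    uniq = np.unique(x)
    out: list[float] = []
    for q, kv in zip(quantiles, knots):
        cand = kv
        if cand in out:
            if q < 0.5:
                lower = uniq[uniq < min(out)]
                cand = float(lower[-1]) if len(lower) else cand
            else:
                higher = uniq[uniq > max(out)]
                cand = float(higher[0]) if len(higher) else cand
        out.append(cand)
    if len(set(out)) != len(out):
        raise ValueError(f"could not place distinct knots on {len(uniq)} unique values")
    log.info("knot quantiles collided; using nearest distinct knots %s", out)
    return tuple(out)


def fit_rcs(
    table: pd.DataFrame,
    outcome: str,
    spec: CovariateSpec | None = None,
    hours_column: str = "sleep_hours",
    knot_quantiles: tuple[float, ...] = (0.10, 0.50, 0.90),
    reference_hours: float = 7.0,
    grid: np.ndarray | None = None,
) -> RCSFit:
    """Spline dose-response with overall (2-df) and nonlinear (1-df) Wald tests."""
    spec = spec or CovariateSpec()
    hours = table[hours_column].to_numpy(dtype=float)
    if len(np.unique(hours)) < 3:
        raise ValueError("need at least 3 distinct hour values for a 3-knot spline")
    knots = _distinct_quantile_knots(hours, knot_quantiles)
    B = rcs_basis(hours, knots)
    n_spline = B.shape[1]
    spline_names = ["rcs_linear"] + [f"rcs_nonlin{j}" for j in range(1, n_spline)]
    X = pd.concat(
        [
            pd.DataFrame(B, columns=spline_names, index=table.index),
            _covariate_design(table, spec),
        ],
        axis=1,
    )
    res = _ols(table[outcome].to_numpy(dtype=float), X)

    names = list(res.params.index)
    idx = [names.index(nm) for nm in spline_names]
    R_all = np.zeros((n_spline, len(names)))
    for r, i in enumerate(idx):
        R_all[r, i] = 1.0
    p_overall = float(res.wald_test(R_all, use_f=False, scalar=True).pvalue)
    R_nl = R_all[1:, :]
    p_nonlinear = float(res.wald_test(R_nl, use_f=False, scalar=True).pvalue)

    coef = res.params.to_numpy()[idx]
    V = res.cov_params().to_numpy()[np.ix_(idx, idx)]
    if grid is None:
        grid = np.arange(float(hours.min()), float(hours.max()) + 1e-9, 0.25)
    Bg = rcs_basis(np.asarray(grid, dtype=float), knots)
    Br = rcs_basis(np.array([reference_hours]), knots)
    D = Bg - Br  # anchored contrast basis
    est = D @ coef
    se = np.sqrt(np.einsum("ij,jk,ik->i", D, V, D))
    curve = pd.DataFrame(
        {
            "hours": np.asarray(grid, dtype=float),
            "estimate": est,
            "ci_low": est - Z95 * se,
            "ci_high": est + Z95 * se,
        }
    )
    return RCSFit(
        outcome=outcome,
        knots=knots,
        coefficients=coef,
        covariance=V,
        reference_hours=reference_hours,
        curve=curve,
        p_overall=p_overall,
        p_nonlinear=p_nonlinear,
        n=int(res.nobs),
    )


def interaction_wald_test(
    table: pd.DataFrame,
    outcome: str,
    stratum_column: str,
    spec: CovariateSpec | None = None,
    category_column: str = "sleep_category",
) -> tuple[float, dict[str, LinearModelResult]]:
    """Joint Wald test on category x stratum product terms.

    Returns the interaction p-value and per-stratum categorical refits.
    Strata with an empty duration category are reported in the error.
    """
    spec = spec or CovariateSpec()
    strata = [s for s in pd.unique(table[stratum_column].dropna())]
    if len(strata) < 2:
        raise ValueError(f"need >= 2 strata in {stratum_column!r}, got {strata}")
    counts = pd.crosstab(table[stratum_column], table[category_column])
    if (counts < 1).any().any():
        empty = [
            (str(s), str(c))
            for s in counts.index
            for c in counts.columns
            if counts.loc[s, c] < 1
        ]
        raise ValueError(f"empty stratum x category cells: {empty}")

    dummies = _category_dummies(table[category_column])
    parts = [dummies, _covariate_design(table, spec)]
    base = sorted(map(str, strata))[0]
    product_names: list[str] = []
    for s in sorted(map(str, strata)):
        if s == base:
            continue
        ind = (table[stratum_column].astype(str) == s).astype(float)
        parts.append(ind.rename(f"stratum[{s}]").to_frame())
        prods = dummies.mul(ind, axis=0)
        prods.columns = [f"{c}:stratum[{s}]" for c in dummies.columns]
        product_names.extend(prods.columns)
        parts.append(prods)
    X = pd.concat(parts, axis=1)
    res = _ols(table[outcome].to_numpy(dtype=float), X)
    names = list(res.params.index)
    R = np.zeros((len(product_names), len(names)))
    for r, nm in enumerate(product_names):
        R[r, names.index(nm)] = 1.0
    p_int = float(res.wald_test(R, use_f=False, scalar=True).pvalue)

    per_stratum = {
        str(s): fit_category_model(
            table.loc[table[stratum_column] == s], outcome, spec, category_column
        )
        for s in strata
    }
    return p_int, per_stratum
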