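"""Klemera-Doubal biological age.

The estimator regresses each biomarker on chronological age in a
reference population, x_j = q_j + k_j * CA + e_j with residual scale s_j,
and combines the per-biomarker age estimates (x_j - q_j)/k_j with
inverse-variance weights (k_j/s_j)^2:

    BA_E = sum_j (x_j - q_j) k_j / s_j^2  /  sum_j (k_j / s_j)^2.

The corrected estimator additionally treats chronological age as a
pseudo-biomarker with weight 1/s_BA^2, where s_BA^2 is the variance of
the biological-age estimate derived from the reference cohort:

    BA_EC = [ sum_j (x_j - q_j) k_j / s_j^2 + CA / s_BA^2 ]
            / [ sum_j (k_j / s_j)^2 + 1 / s_BA^2 ].

Either way, a noiseless profile x_j = q_j + k_j * CA scores exactly CA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..panel import BiomarkerPanel

log = logging.getLogger(__name__)


@dataclass
class KDMModel:
    """Fitted Klemera-Doubal parameters.

    ``biomarkers`` lists the analytes retained after the slope floor;
    ``q``, ``k``, ``s`` are the per-analyte intercepts, age slopes, and
    residual scales; ``s2_ba`` is the variance of the biological-age
    estimate used to weight the chronological-age term.
    """

    biomarkers: list[str]
    q: dict[str, float]
    k: dict[str, float]
    s: dict[str, float]
    s2_ba: float
    excluded: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "biomarkers": self.biomarkers,
            "q": self.q,
            "k": self.k,
            "s": self.s,
            "s2_ba": self.s2_ba,
            "excluded": self.excluded,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KDMModel":
        return cls(**d)


def fit_kdm(
    reference: pd.DataFrame,
    panel: BiomarkerPanel,
    slope_floor: float = 1e-6,
    age_column: str = "age",
) -> KDMModel:
    """Fit the per-biomarker age regressions on a reference cohort.

    Biomarkers whose |slope| falls below ``slope_floor`` (in analyte units
    per year) or whose residual scale collapses are excluded with a logged
    warning rather than failing: a flat biomarker carries no age signal
    and would otherwise blow up the (x - q)/k age estimate.
    """
    age = reference[age_column].to_numpy(dtype=float)
    if np.ptp(age) == 0:
        raise ValueError("reference cohort has constant chronological age")
    if len(panel) < 1:
        raise ValueError("panel must contain at least one biomarker")

    q: dict[str, float] = {}
    k: dict[str, float] = {}
    s: dict[str, float] = {}
    r: dict[str, float] = {}
    excluded: list[str] = []
    for name in panel.names:
        x = reference[name].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise ValueError(f"biomarker {name!r} has zero variance in the reference")
        slope, intercept = np.polyfit(age, x, 1)
        resid = x - (intercept + slope * age)
        scale = float(np.sqrt(np.sum(resid**2) / max(len(x) - 2, 1)))
        if abs(slope) < slope_floor:
            log.warning("excluding biomarker %s from KDM (slope %.3g below floor %.3g)",
                        name, slope, slope_floor)
            excluded.append(name)
            continue
        if scale < 1e-12:
            # exact fit (e.g. collinear reference points): keep the biomarker
            # but clamp the scale so the inverse-variance weight stays finite
            log.warning("biomarker %s fits age exactly; clamping scale to 1e-12", name)
            scale = 1e-12
        q[name] = float(intercept)
        k[name] = float(slope)
        s[name] = scale
        r[name] = float(np.corrcoef(age, x)[0, 1])
    if not q:
        raise ValueError("no biomarker survived the slope floor")

    retained = list(q)
    model = KDMModel(biomarkers=retained, q=q, k=k, s=s, s2_ba=np.inf, excluded=excluded)
    # characteristic correlation: weighted mean of the per-biomarker age
    # correlations with weights r/sqrt(1-r^2)
    rv = np.array([r[n] for n in retained])
    rv = np.clip(np.abs(rv), 1e-12, 1 - 1e-12)
    w = rv / np.sqrt(1.0 - rv**2)
    r_char = float(np.sum(rv * w) / np.sum(w))
    ba_e = score_kdm(model, reference, use_chronological_term=False, age_column=age_column)
    m = len(retained)
    s2 = float(np.mean((ba_e - age) ** 2)) - ((1.0 - r_char**2) / r_char**2) * (
        np.ptp(age) ** 2 / (12.0 * m)
    )
    if not np.isfinite(s2) or s2 <= 0:
        # degenerate (e.g. near-perfect biomarkers): fall back to the raw MSE
        s2 = max(float(np.mean((ba_e - age) ** 2)), 1e-8)
    model.s2_ba = s2
    return model


def score_kdm(
    model: KDMModel,
    target: pd.DataFrame,
    use_chronological_term: bool = True,
    age_column: str = "age",
) -> pd.Series:
    """Score the Klemera-Doubal age on a target cohort.

    With ``use_chronological_term`` (default), chronological age enters as
    a pseudo-biomarker weighted by 1/s2_ba -- the corrected estimator.
    """
    missing = [n for n in model.biomarkers if n not in target.columns]
    if missing:
        raise ValueError(f"target cohort lacks model biomarkers: {missing}")
    num = np.zeros(len(target))
    den = 0.0
    for name in model.biomarkers:
        x = target[name].to_numpy(dtype=float)
        num += (x - model.q[name]) * model.k[name] / model.s[name] ** 2
        den += (model.k[name] / model.s[name]) ** 2
    if use_chronological_term:
        ca = target[age_column].to_numpy(dtype=float)
        num = num + ca / model.s2_ba
        den = den + 1.0 / model.s2_ba
    return pd.Series(num / den, index=target.index, name="kdm")
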