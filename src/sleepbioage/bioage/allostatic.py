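"""Allostatic load: fraction of analytes in their at-risk quartile.

For nine of the ten analytes, values at or above the 75th percentile of
the scoring cohort's distribution count as at-risk; for the albumin-like
analyte, values at or below the 25th percentile do. AL is the at-risk
count divided by the panel size, so it ranges over {0, 0.1, ..., 1.0}
for a ten-analyte panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..panel import BiomarkerPanel

log = logging.getLogger(__name__)


@dataclass
class ALThresholds:
    biomarkers: list[str]
    cutoffs: dict[str, float]
    high_risk_at_top: dict[str, bool]

    def to_dict(self) -> dict:
        return self.__dict__.copy()

    @classmethod
    def from_dict(cls, d: dict) -> "ALThresholds":
        return cls(**d)


def fit_al_thresholds(cohort: pd.DataFrame, panel: BiomarkerPanel) -> ALThresholds:
    """Quartile cutoffs per analyte, honouring each risk direction."""
    if len(cohort) < 4:
        raise ValueError("need at least 4 participants to place quartile cutoffs")
    cutoffs: dict[str, float] = {}
    direction: dict[str, bool] = {}
    for analyte in panel:
        x = cohort[analyte.name].to_numpy(dtype=float)
        pct = 75.0 if analyte.high_risk_at_top else 25.0
        cut = float(np.percentile(x, pct))
        if np.ptp(x) == 0:
            log.warning("analyte %s is constant; AL threshold degenerate", analyte.name)
        cutoffs[analyte.name] = cut
        direction[analyte.name] = analyte.high_risk_at_top
    return ALThresholds(
        biomarkers=list(panel.names), cutoffs=cutoffs, high_risk_at_top=direction
    )


def score_al(thresholds: ALThresholds, target: pd.DataFrame) -> pd.Series:
    """At-risk fraction per participant (always a multiple of 1/panel size)."""
    missing = [n for n in thresholds.biomarkers if n not in target.columns]
    if missing:
        raise ValueError(f"target cohort lacks panel analytes: {missing}")
    at_risk = np.zeros(len(target), dtype=int)
    for name in thresholds.biomarkers:
        x = target[name].to_numpy(dtype=float)
        cut = thresholds.cutoffs[name]
        if thresholds.high_risk_at_top[name]:
            at_risk += (x >= cut).astype(int)
        else:
            at_risk += (x <= cut).astype(int)
    return pd.Series(at_risk / len(thresholds.biomarkers), index=target.index, name="al")
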