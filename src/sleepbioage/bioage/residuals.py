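"""Age-acceleration residuals.

PhenoAge and KDM are age-scale metrics, so their deviation from what is
expected at a given chronological age is isolated by regressing each
metric on chronological age and keeping the residual. HD and AL already
measure deviation from a reference population and pass through unchanged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def compute_age_acceleration(
    metrics: pd.DataFrame,
    age_column: str = "age",
    metric_columns: tuple[str, ...] = ("phenoage", "kdm"),
) -> pd.DataFrame:
    """Append ``<metric>_residual`` columns (OLS residual on age).

    Residuals are exactly mean-zero and uncorrelated with chronological
    age by the normal equations.
    """
    n_ok = metrics[list(metric_columns)].notna().all(axis=1) & metrics[age_column].notna()
    if n_ok.sum() < 3:
        raise ValueError("need at least 3 participants with finite metrics")
    age = metrics[age_column].to_numpy(dtype=float)
    if np.ptp(age[n_ok.to_numpy()]) == 0:
        raise ValueError("chronological age is constant; residuals undefined")
    out = metrics.copy()
    for col in metric_columns:
        y = metrics[col].to_numpy(dtype=float)
        slope, intercept = np.polyfit(age, y, 1)
        out[f"{col}_residual"] = y - (intercept + slope * age)
    return out
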