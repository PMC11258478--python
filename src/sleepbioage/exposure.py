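"""Sleep exposure coding, the composite sleep score, and cohort exclusions.

Habitual sleep duration is analysed in five questionnaire categories
(<=5, 6, 7, 8, >=9 h/day) with 7 h/day as the reference. Questionnaire
responses are effectively integers; the rounding rule below exists only
so synthetic continuous durations are classifiable.

The composite sleep score sums five binary low-risk factors (morning
chronotype, 7-8 h duration, no frequent insomnia, no snoring, no
frequent daytime sleepiness); a score of 3-5 is a healthy sleep pattern
and <=2 a poor one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SLEEP_CATEGORIES = ["le5", "6", "7", "8", "ge9"]
REFERENCE_CATEGORY = "7"
CATEGORY_LABELS = {"le5": "≤5", "6": "6", "7": "7", "8": "8", "ge9": "≥9"}

LOW_RISK_FLAGS = [
    "chronotype_morning",
    "no_insomnia",
    "no_daytime_sleepiness",
    "no_snoring",
]


def categorize_sleep_duration(hours: float) -> str:
    """Map hours/day to one of the five reporting categories.

    hours <= 5.49 -> "le5"; >= 8.5 -> "ge9"; otherwise round to the
    nearest integer (half hours round up, so 6.5 -> "7").
    """
    if not math.isfinite(hours):
        raise ValueError(f"non-finite sleep duration: {hours}")
    if not (0.0 < hours < 24.0):
        raise ValueError(f"sleep duration must lie in (0, 24) h/day, got {hours}")
    if hours <= 5.49:
        return "le5"
    if hours >= 8.5:
        return "ge9"
    return str(int(math.floor(hours + 0.5)))


def categorize_sleep_durations(hours: pd.Series) -> pd.Series:
    cats = hours.map(categorize_sleep_duration)
    return pd.Series(
        pd.Categorical(cats, categories=SLEEP_CATEGORIES),
        index=hours.index,
        name="sleep_category",
    )


def compute_sleep_score(table: pd.DataFrame) -> pd.DataFrame:
    """Append ``sleep_score`` (0-5) and ``sleep_pattern`` columns.

    The duration factor is low-risk when the category is 7 or 8 h/day.
    Rows missing any factor are dropped (the caller sees the reduced
    table; use :func:`apply_exclusions` for ledgered filtering).
    """
    required = LOW_RISK_FLAGS + ["sleep_category"]
    missing_cols = [c for c in required if c not in table.columns]
    if missing_cols:
        raise ValueError(f"missing sleep factor columns: {missing_cols}")
    complete = table.dropna(subset=required)
    duration_ok = complete["sleep_category"].isin(["7", "8"]).astype(int)
    score = complete[LOW_RISK_FLAGS].astype(int).sum(axis=1) + duration_ok
    out = complete.copy()
    out["sleep_score"] = score
    out["sleep_pattern"] = np.where(score >= 3, "healthy", "poor")
    return out


@dataclass
class CovariateSpec:
    """Ordered adjustment set with coding per variable.

    ``continuous`` enter as-is; ``categorical`` are dummy-coded against
    the stated reference level.
    """

    continuous: list[str] = field(
        default_factory=lambda: ["age", "bmi", "tdi", "diet_score"]
    )
    binary: list[str] = field(
        default_factory=lambda: [
            "sex",
            "smoking",
            "drinking",
            "education",
            "disease_history",
            "family_history",
            "medication",
        ]
    )
    categorical: dict[str, int] = field(
        default_factory=lambda: {"phys_activity": 0, "health_rating": 0}
    )

    @property
    def columns(self) -> list[str]:
        return self.continuous + self.binary + list(self.categorical)


# exclusion criteria applied in flowchart order: (name, columns that must be
# complete) or (name, predicate)
def apply_exclusions(
    cohort: pd.DataFrame,
    sleep_columns: list[str] | None = None,
    biomarker_columns: list[str] | None = None,
    covariate_columns: list[str] | None = None,
    energy_bounds: tuple[float, float] = (500.0, 6000.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Complete-case filtering with a per-criterion exclusion ledger.

    Criteria are applied in order: missing sleep data, missing biomarker
    or mediator data, pregnancy / implausible energy intake, missing
    covariates. Returns the filtered table and a ledger with the count
    removed at each step.
    """
    sleep_columns = sleep_columns or ["sleep_hours"] + LOW_RISK_FLAGS
    biomarker_columns = biomarker_columns or ["cysc", "ggt"]
    covariate_columns = covariate_columns or CovariateSpec().columns

    def _complete(cols: list[str]) -> pd.Series:
        cols = [c for c in cols if c in cohort.columns]
        return cohort[cols].notna().all(axis=1)

    pregnant = (
        cohort["pregnant"].fillna(0).astype(bool)
        if "pregnant" in cohort.columns
        else pd.Series(False, index=cohort.index)
    )
    energy_ok = (
        cohort["energy_kcal"].between(*energy_bounds)
        if "energy_kcal" in cohort.columns
        else pd.Series(True, index=cohort.index)
    )
    criteria = [  # (name, keep mask over the ORIGINAL cohort)
        ("missing_sleep_data", _complete(sleep_columns)),
        ("missing_biomarker_data", _complete(biomarker_columns)),
        ("pregnant_or_implausible_energy", ~pregnant & energy_ok),
        ("missing_covariate_data", _complete(covariate_columns)),
    ]
    table = cohort
    ledger_rows = []
    for name, keep in criteria:
        keep = keep.loc[table.index]
        removed = int((~keep).sum())
        table = table.loc[keep]
        ledger_rows.append(
            {"criterion": name, "removed": removed, "remaining": int(len(table))}
        )
    if len(table) == 0:
        raise ValueError("all participants excluded; check the exclusion configuration")
    ledger = pd.DataFrame(ledger_rows)
    return table, ledger
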