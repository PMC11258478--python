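"""Configuration objects for cohort synthesis and the pipeline.

``SyntheticConfig`` encodes the generative assumptions the analysis chain
is exercised under: biomarkers drifting linearly with age plus Gaussian
noise, a Gompertz mortality hazard for the reference cohort, and a
U-shaped effect of habitual sleep duration on the biomarker profile with
its minimum near 7 h/day, routed partly through the two mediators
(cystatin C and GGT) in configurable proportions.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

from .panel import BiomarkerPanel, default_panel

# Per-analyte generative parameters for the default panel:
# mean value at age 50, drift per year of age, residual SD.
# Magnitudes are typical adult clinical-chemistry values; drifts are small
# relative to cross-sectional spread, as in real cohorts.
DEFAULT_BIOMARKER_PARAMS: dict[str, tuple[float, float, float]] = {
    "albumin": (4.50, -0.0050, 0.25),
    "alkaline_phosphatase": (72.0, 0.25, 15.0),
    "creatinine": (0.88, 0.0030, 0.15),
    "crp_log": (0.30, 0.0100, 0.80),
    "hba1c": (5.40, 0.0120, 0.35),
    "wbc_count": (6.80, 0.0100, 1.40),
    "lymphocyte_pct": (31.0, 0.0500, 6.00),
    "mean_cell_volume": (90.0, 0.0200, 4.00),
    "rdw": (13.2, 0.0100, 0.90),
    "glucose": (96.0, 0.1500, 12.0),
}

# Habitual sleep duration: five reporting categories with marginal
# probabilities shaped like a large population questionnaire (mode at 7 h),
# each category realized on a 0.5-h grid.
SLEEP_CATEGORY_PROBS: dict[str, float] = {
    "le5": 0.044,
    "6": 0.179,
    "7": 0.395,
    "8": 0.304,
    "ge9": 0.078,
}
SLEEP_CATEGORY_GRIDS: dict[str, tuple[float, ...]] = {
    "le5": (4.0, 4.5, 5.0),
    "6": (5.5, 6.0),
    "7": (6.5, 7.0),
    "8": (7.5, 8.0),
    "ge9": (8.5, 9.0, 9.5, 10.0),
}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic-cohort generators.

    Attributes
    ----------
    n_reference, n_target : int
        Cohort sizes (reference carries mortality follow-up for metric
        training; target carries sleep exposures and mediators).
    seed : int
        Base seed; every generator derives its own stream from it.
    age_range : (float, float)
        Uniform age span in years.
    biomarker_age_slopes, biomarker_noise_sd, biomarker_means_at_50 :
        Per-analyte generative parameters, keyed by analyte name.
    sleep_effect_curvature : float
        Biomarker shift, in units of each analyte's noise SD, per
        (hours - 7)^2. Positive curvature produces the U shape.
    mediated_fraction_cysc, mediated_fraction_ggt : float
        Fractions of the sleep -> biomarker effect routed through
        cystatin C and GGT respectively (the remainder is direct).
    mortality_gompertz_shape : float
        Per-year log-hazard slope of the Gompertz mortality model.
    mortality_log_rate : float
        Log baseline hazard at age 0 (per year).
    mortality_biomarker_weight : float
        Log-hazard increment per risk-signed SD of each biomarker.
    burden_loading : float
        Loading of a shared standard-normal physiological-burden factor
        on every analyte (in risk-signed noise-SD units); induces the
        positive inter-biomarker correlation real panels show.
    censoring_horizon : float
        Administrative censoring time in years of follow-up.
    snp_count, missing_rate : genotype table shape and missingness.
    """

    n_reference: int = 5000
    n_target: int = 5000
    seed: int = 20240001
    age_range: tuple[float, float] = (38.0, 73.0)
    biomarker_age_slopes: dict[str, float] = field(default_factory=dict)
    biomarker_noise_sd: dict[str, float] = field(default_factory=dict)
    biomarker_means_at_50: dict[str, float] = field(default_factory=dict)
    sleep_effect_curvature: float = 0.05
    mediated_fraction_cysc: float = 0.35
    mediated_fraction_ggt: float = 0.07
    mortality_gompertz_shape: float = 0.085
    mortality_log_rate: float = -9.8
    mortality_biomarker_weight: float = 0.10
    burden_loading: float = 0.20
    censoring_horizon: float = 27.0
    snp_count: int = 112
    missing_rate: float = 0.02
    # mediator generative parameters (baseline at age 50, age drift, noise SD,
    # and signal carried per (hours-7)^2)
    cysc_mean: float = 0.90
    cysc_age_slope: float = 0.004
    cysc_noise_sd: float = 0.10
    cysc_signal_per_h2: float = 0.05
    ggt_mean: float = 35.0
    ggt_age_slope: float = 0.10
    ggt_noise_sd: float = 12.0
    ggt_signal_per_h2: float = 3.0
    round_sleep_to_integers: bool = False
    panel: BiomarkerPanel = field(default_factory=default_panel)

    def __post_init__(self) -> None:
        for name, (mean, slope, sd) in DEFAULT_BIOMARKER_PARAMS.items():
            self.biomarker_means_at_50.setdefault(name, mean)
            self.biomarker_age_slopes.setdefault(name, slope)
            self.biomarker_noise_sd.setdefault(name, sd)
        self.validate()

    def validate(self) -> None:
        if self.n_reference < 2 or self.n_target < 2:
            raise ValueError("cohort sizes must be >= 2")
        lo, hi = self.age_range
        if not (math.isfinite(lo) and math.isfinite(hi)) or lo >= hi:
            raise ValueError("age_range must be finite with low < high")
        for frac_name in ("mediated_fraction_cysc", "mediated_fraction_ggt", "missing_rate"):
            v = getattr(self, frac_name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{frac_name} must lie in [0, 1], got {v}")
        if self.mediated_fraction_cysc + self.mediated_fraction_ggt > 1.0 + 1e-12:
            raise ValueError("mediated fractions must sum to at most 1")
        if self.snp_count < 1:
            raise ValueError("snp_count must be >= 1")
        if self.censoring_horizon <= 0:
            raise ValueError("censoring_horizon must be positive")
        scalars = [
            self.sleep_effect_curvature,
            self.mortality_gompertz_shape,
            self.mortality_log_rate,
            self.mortality_biomarker_weight,
        ]
        scalars += list(self.biomarker_age_slopes.values())
        scalars += list(self.biomarker_noise_sd.values())
        if not all(math.isfinite(v) for v in scalars):
            raise ValueError("configuration values must be finite")
        for name, sd in self.biomarker_noise_sd.items():
            if sd < 0:
                raise ValueError(f"negative noise SD for {name}")
        for name in self.panel.names:
            if name not in self.biomarker_age_slopes:
                raise ValueError(f"no generative parameters for analyte {name!r}")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["panel"] = [dataclasses.asdict(a) for a in self.panel.analytes]
        d["age_range"] = list(self.age_range)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SyntheticConfig":
        d = dict(d)
        if "panel" in d:
            from .panel import Analyte

            d["panel"] = BiomarkerPanel(tuple(Analyte(**a) for a in d["panel"]))
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "SyntheticConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
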