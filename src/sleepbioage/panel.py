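"""Blood-chemistry biomarker panel description.

The four predicted-age metrics are all built on the same panel of ten
blood-chemistry analytes. Each analyte carries a risk direction: for nine
of the ten, values in the top quartile of the distribution are counted as
"at risk"; albumin is the exception, where the bottom quartile carries the
risk (low serum albumin marks frailty and inflammation). The panel is
configurable -- any ten analytes with declared directions work -- but the
default mirrors the clinical-chemistry panels used throughout the
biological-age literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Analyte:
    """One blood-chemistry analyte.

    Parameters
    ----------
    name : str
        Column name in participant tables.
    units : str
        Reporting units (informational).
    high_risk_at_top : bool
        True if the top quartile is the at-risk quartile (the usual case);
        False for albumin-like analytes where low values carry risk.
    log_transform : bool
        Whether the analyte is modelled on the natural-log scale.
    """

    name: str
    units: str
    high_risk_at_top: bool = True
    log_transform: bool = False


@dataclass(frozen=True)
class BiomarkerPanel:
    """Ordered collection of analytes used by every metric."""

    analytes: tuple[Analyte, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [a.name for a in self.analytes]
        if len(set(names)) != len(names):
            raise ValueError("analyte names must be unique")
        n_bottom = sum(not a.high_risk_at_top for a in self.analytes)
        if n_bottom > 1:
            raise ValueError(
                "at most one albumin-like analyte may carry bottom-quartile risk "
                f"(got {n_bottom})"
            )

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.analytes]

    @property
    def risk_signs(self) -> list[int]:
        """+1 where high values are risky, -1 for the albumin-like analyte."""
        return [1 if a.high_risk_at_top else -1 for a in self.analytes]

    def __len__(self) -> int:
        return len(self.analytes)

    def __iter__(self):
        return iter(self.analytes)


def default_panel() -> BiomarkerPanel:
    """Ten-analyte clinical chemistry panel.

    Albumin is the single bottom-quartile-risk analyte; C-reactive protein
    is modelled on the log scale (heavily right-skewed in serum).
    """
    return BiomarkerPanel(
        analytes=(
            Analyte("albumin", "g/dL", high_risk_at_top=False),
            Analyte("alkaline_phosphatase", "U/L"),
            Analyte("creatinine", "mg/dL"),
            Analyte("crp_log", "ln(mg/L)", log_transform=True),
            Analyte("hba1c", "%"),
            Analyte("wbc_count", "10^9/L"),
            Analyte("lymphocyte_pct", "%"),
            Analyte("mean_cell_volume", "fL"),
            Analyte("rdw", "%"),
            Analyte("glucose", "mg/dL"),
        )
    )
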