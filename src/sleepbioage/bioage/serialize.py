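"""Versioned JSON serialization for the trained metric models."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import pandas as pd

from ..panel import Analyte, BiomarkerPanel
from .allostatic import ALThresholds
from .hd import HDModel
from .kdm import KDMModel
from .phenoage import PhenoAgeModel

FORMAT_VERSION = 1


def panel_hash(panel: BiomarkerPanel) -> str:
    payload = json.dumps(
        [[a.name, a.units, a.high_risk_at_top, a.log_transform] for a in panel],
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class TrainedMetricModels:
    """All fitted metric parameters plus training-cohort provenance."""

    panel: BiomarkerPanel
    kdm: KDMModel
    phenoage: PhenoAgeModel
    hd: HDModel
    al: ALThresholds | None
    training_summary: dict

    def to_json(self, path: str) -> None:
        doc = {
            "format_version": FORMAT_VERSION,
            "panel_hash": panel_hash(self.panel),
            "panel": [
                {
                    "name": a.name,
                    "units": a.units,
                    "high_risk_at_top": a.high_risk_at_top,
                    "log_transform": a.log_transform,
                }
                for a in self.panel
            ],
            "kdm": self.kdm.to_dict(),
            "phenoage": self.phenoage.to_dict(),
            "hd": self.hd.to_dict(),
            "al": self.al.to_dict() if self.al is not None else None,
            "training_summary": self.training_summary,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "TrainedMetricModels":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format_version") != FORMAT_VERSION:
            raise ValueError(f"unsupported model format: {doc.get('format_version')}")
        panel = BiomarkerPanel(tuple(Analyte(**a) for a in doc["panel"]))
        return cls(
            panel=panel,
            kdm=KDMModel.from_dict(doc["kdm"]),
            phenoage=PhenoAgeModel.from_dict(doc["phenoage"]),
            hd=HDModel.from_dict(doc["hd"]),
            al=ALThresholds.from_dict(doc["al"]) if doc["al"] is not None else None,
            training_summary=doc["training_summary"],
        )


def training_summary(reference: pd.DataFrame) -> dict:
    return {
        "n": int(len(reference)),
        "age_mean": float(reference["age"].mean()),
        "age_min": float(reference["age"].min()),
        "age_max": float(reference["age"].max()),
        "events": int(reference["death"].sum()) if "death" in reference else None,
    }
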