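"""Homeostatic dysregulation: Mahalanobis distance from a healthy reference.

Analytes are standardized by the healthy subsample's center and scale;
the metric is the Mahalanobis distance of a participant's standardized
profile from the healthy subsample's mean under its covariance:

    HD = sqrt((z - mu)^T Sigma^{-1} (z - mu)).

Distance is zero at the reference centroid, nonnegative everywhere, and
invariant under any invertible linear reparameterization of the
biomarker space applied consistently to reference and target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from ..panel import BiomarkerPanel

log = logging.getLogger(__name__)


@dataclass
class HDModel:
    biomarkers: list[str]
    center: dict[str, float]
    scale: dict[str, float]
    reference_mean: list[float]  # of standardized values
    reference_covariance: list[list[float]]
    healthy_reference_definition: str = "full cohort"
    log1p_transform: bool = False

    def to_dict(self) -> dict:
        return self.__dict__.copy()

    @classmethod
    def from_dict(cls, d: dict) -> "HDModel":
        return cls(**d)


def _check_covariance(cov: np.ndarray, names: list[str]) -> None:
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals.min() <= 1e-10:
        # name the most collinear pair to make the failure actionable
        sd = np.sqrt(np.diag(cov))
        corr = cov / np.outer(sd, sd)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise ValueError(
            "singular biomarker covariance in the healthy reference; most "
            f"collinear pair: {names[i]!r} and {names[j]!r} "
            f"(correlation {corr[i, j]:.4f})"
        )


def fit_hd(
    reference: pd.DataFrame,
    panel: BiomarkerPanel,
    healthy_filter: Callable[[pd.DataFrame], pd.Series] | None = None,
    log1p_transform: bool = False,
) -> HDModel:
    """Estimate the healthy-reference centroid and covariance.

    ``healthy_filter`` maps the reference table to a boolean mask
    selecting the healthy subsample; by default everyone is used. If the
    filter leaves too few rows for an invertible covariance the full
    cohort is used instead (logged).
    """
    names = panel.names
    if healthy_filter is not None:
        mask = healthy_filter(reference).astype(bool)
        healthy = reference.loc[mask]
        definition = "custom filter"
        if len(healthy) <= len(names):
            log.warning(
                "healthy subsample too small (%d rows for %d analytes); "
                "falling back to the full reference cohort",
                len(healthy), len(names),
            )
            healthy = reference
            definition = "full cohort (filter fallback)"
    else:
        healthy = reference
        definition = "full cohort"
    if len(healthy) <= len(names):
        raise ValueError(
            f"healthy subsample has {len(healthy)} rows; need more than "
            f"{len(names)} for an invertible covariance"
        )

    X = healthy[names].to_numpy(dtype=float)
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    if (scale == 0).any():
        bad = [n for n, s in zip(names, scale) if s == 0]
        raise ValueError(f"zero-variance analytes in healthy reference: {bad}")
    Z = (X - center) / scale
    mu = Z.mean(axis=0)
    cov = np.cov(Z, rowvar=False)
    _check_covariance(cov, names)
    return HDModel(
        biomarkers=list(names),
        center={n: float(c) for n, c in zip(names, center)},
        scale={n: float(s) for n, s in zip(names, scale)},
        reference_mean=mu.tolist(),
        reference_covariance=cov.tolist(),
        healthy_reference_definition=definition,
        log1p_transform=log1p_transform,
    )


def healthy_interval_filter(
    intervals: dict[str, tuple[float, float]]
) -> Callable[[pd.DataFrame], pd.Series]:
    """Healthy = every listed analyte inside its reference interval."""

    def _filter(table: pd.DataFrame) -> pd.Series:
        mask = pd.Series(True, index=table.index)
        for name, (lo, hi) in intervals.items():
            mask &= table[name].between(lo, hi)
        return mask

    return _filter


def score_hd(model: HDModel, target: pd.DataFrame) -> pd.Series:
    """Mahalanobis distance of each participant from the healthy centroid."""
    missing = [n for n in model.biomarkers if n not in target.columns]
    if missing:
        raise ValueError(f"target cohort lacks model biomarkers: {missing}")
    X = target[model.biomarkers].to_numpy(dtype=float)
    center = np.array([model.center[n] for n in model.biomarkers])
    scale = np.array([model.scale[n] for n in model.biomarkers])
    dev = (X - center) / scale - np.asarray(model.reference_mean)
    cov = np.asarray(model.reference_covariance)
    L = np.linalg.cholesky(cov)
    w = np.linalg.solve(L, dev.T)
    hd = np.sqrt(np.sum(w**2, axis=0))
    if model.log1p_transform:
        hd = np.log1p(hd)
    return pd.Series(hd, index=target.index, name="hd")
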