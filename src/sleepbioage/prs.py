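"""Weighted polygenic risk scores from a dosage matrix and weight table.

The score for sample j over SNPs i with effect magnitudes S_i, observed
effect-allele counts G_ij, ploidy P, and per-sample non-missing SNP count
M_j is

    PRS_j = sum_i S_i * G_ij / (P * M_j),

with missing dosages contributing nothing to the numerator and excluded
from M_j. Participants are split at the PRS median for stratified
analyses, ties going to the low stratum.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def compute_prs(
    weights: pd.DataFrame,
    genotypes: pd.DataFrame,
    ploidy: int = 2,
    expected_alleles: pd.Series | None = None,
) -> pd.Series:
    """Per-sample weighted PRS.

    ``weights`` must have columns ``snp_id`` and ``effect_size`` (plus
    ``effect_allele``); ``genotypes`` is samples x SNPs with NaN for
    missing. Every genotype column must match a weight row by id, and when
    ``expected_alleles`` (indexed by snp_id) is given, the weight table's
    effect alleles must agree -- mismatches error rather than auto-flip.
    """
    if weights["snp_id"].duplicated().any():
        dup = weights.loc[weights["snp_id"].duplicated(), "snp_id"].tolist()
        raise ValueError(f"duplicate SNP ids in weight table: {dup}")
    w = weights.set_index("snp_id")
    unmatched = [c for c in genotypes.columns if c not in w.index]
    if unmatched:
        raise ValueError(f"genotype SNPs without weights: {unmatched}")
    if expected_alleles is not None:
        mism = [
            s for s in genotypes.columns
            if w.loc[s, "effect_allele"] != expected_alleles.loc[s]
        ]
        if mism:
            raise ValueError(f"effect-allele mismatch for SNPs: {mism}")

    G = genotypes.to_numpy(dtype=float)
    if np.nanmax(G, initial=0.0) > ploidy or np.nanmin(G, initial=0.0) < 0:
        raise ValueError(f"dosages must lie in [0, {ploidy}]")
    S = w.loc[genotypes.columns, "effect_size"].to_numpy(dtype=float)
    observed = ~np.isnan(G)
    m = observed.sum(axis=1)
    if (m == 0).any():
        bad = genotypes.index[m == 0].tolist()
        raise ValueError(f"samples with no observed SNPs: {bad}")
    numer = np.nansum(G * S, axis=1)
    return pd.Series(numer / (ploidy * m), index=genotypes.index, name="prs")


def split_by_prs_median(prs: pd.Series) -> pd.Series:
    """Binary stratum labels: 'low' for scores at or below the median."""
    if len(prs) < 2:
        raise ValueError("need at least 2 samples to split at the median")
    med = float(prs.median())
    if prs.nunique() == 1:
        log.warning("all PRS values equal; entire cohort assigned to 'low'")
    labels = np.where(prs.to_numpy() <= med, "low", "high")
    return pd.Series(labels, index=prs.index, name="prs_stratum")
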