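"""Selective-sweep localization by normalized relative heterozygosity.

A locus driven to fixation in the affected breeds leaves a footprint of
reduced heterozygosity in cases relative to controls. The scan computes, in
sliding windows along a chromosome, the ratio of mean case heterozygosity to
mean control heterozygosity and normalizes it so that equal heterozygosity
maps to 0, a case deficit to negative values, and a case excess to positive
values:

    normalized = 1 - 1/ratio   if 0 < ratio < 1
    normalized = ratio - 1     otherwise (including ratio = 0, which maps
                               to -1, and ratio >= 1)

The normalization is antisymmetric under inverting the ratio:
``normalize_ratio(1/r) == -normalize_ratio(r)`` for r > 0.

The sweep scan uses its own, looser QC than the association scan (it is a
descriptive statistic): samples with call rate > 75% are kept, then SNPs
with call rate < 95% are removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset

__all__ = [
    "SweepProfile",
    "sweep_qc",
    "heterozygosity_rate",
    "normalize_ratio",
    "sliding_profile",
]

log = logging.getLogger(__name__)

SAMPLE_CALLRATE_MIN = 0.75  # strictly greater-than retained
SNP_CALLRATE_MIN = 0.95  # strictly less-than removed


@dataclass
class SweepProfile:
    """Windowed relative-heterozygosity profile for one chromosome.

    ``windows`` has one row per sliding window: midpoint_bp, het_cases,
    het_controls, ratio, normalized. ratio/normalized are NaN where the
    window is undefined (control heterozygosity 0 with case
    heterozygosity > 0).
    """

    chromosome: str
    window_snps: int
    windows: pd.DataFrame

    def minimum(self) -> pd.Series:
        """The window with the lowest defined normalized value.

        Ties (common in "floor" mode, where every fully swept window sits
        at the same floor) are broken by preferring complete case fixation
        (ratio exactly 0) and then the strongest contrast (largest control
        heterozygosity).
        """
        defined = self.windows.dropna(subset=["normalized"])
        if defined.empty:
            raise ValueError("no window has a defined normalized value")
        low = defined["normalized"].min()
        tied = defined[defined["normalized"] <= low + 1e-12]
        swept = tied[tied["ratio"] == 0]
        if not swept.empty:
            tied = swept
        return tied.loc[tied["het_controls"].idxmax()]


def sweep_qc(dataset: GenotypeDataset) -> GenotypeDataset:
    """Apply the sweep-scan call-rate filters.

    Keeps samples with call rate strictly above 75% (over all SNPs), then
    removes SNPs with call rate below 95% on the retained samples.
    """
    callrate = 1.0 - dataset.sample_missing_rate()
    keep = callrate > SAMPLE_CALLRATE_MIN
    ds = dataset.take_samples(np.flatnonzero(keep))
    if ds.n_samples == 0:
        raise ValueError("sweep QC removed every sample")
    snp_keep = ds.snp_call_rate() >= SNP_CALLRATE_MIN
    ds = ds.take_snps(np.flatnonzero(snp_keep))
    if ds.n_snps == 0:
        raise ValueError("sweep QC removed every SNP")
    log.info(
        "sweep QC: samples %d -> %d, SNPs %d -> %d",
        dataset.n_samples, ds.n_samples, dataset.n_snps, ds.n_snps,
    )
    return ds


def heterozygosity_rate(calls: np.ndarray) -> float:
    """Fraction of non-missing calls that are heterozygous.

    NaN if every call is missing (propagated as missing downstream).
    """
    calls = np.asarray(calls)
    called = calls != MISSING
    n = called.sum()
    if n == 0:
        return float("nan")
    return float((calls[called] == 1).mean())


def normalize_ratio(ratio):
    """Map a heterozygosity ratio onto the signed relative scale.

    Scalar or array. ``1 - 1/ratio`` for ratios strictly between 0 and 1,
    ``ratio - 1`` otherwise; negative input raises. Note ratio = 0 (cases
    completely homozygous) falls in the "otherwise" branch and maps to -1,
    the same value as ratio = 0.5; see `sliding_profile` for the optional
    floor treatment of fully swept windows.
    """
    arr = np.asarray(ratio, dtype=np.float64)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise ValueError("ratio must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where((arr > 0) & (arr < 1), 1.0 - 1.0 / np.where(arr > 0, arr, 1.0), arr - 1.0)
    out = np.where(np.isnan(arr), np.nan, out)
    return float(out) if np.isscalar(ratio) or np.ndim(ratio) == 0 else out


def _group_het_rates(dataset: GenotypeDataset, mask: np.ndarray, cols: np.ndarray) -> np.ndarray:
    calls = dataset.calls[np.ix_(mask, cols)]
    called = calls != MISSING
    n = called.sum(axis=0)
    het = ((calls == 1) & called).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, het / np.maximum(n, 1), np.nan)


def sliding_profile(
    dataset: GenotypeDataset,
    chromosome: str,
    window_snps: int = 5,
    zero_mode: str = "literal",
) -> SweepProfile:
    """Normalized relative heterozygosity in sliding windows of SNPs.

    Windows advance one SNP at a time. Within each window the per-SNP
    heterozygosity rates are averaged separately in cases and controls
    (window means of rates, not of per-SNP ratios), then
    ratio = het_cases / het_controls and normalized = `normalize_ratio`.
    Window midpoints are the mean of the window's SNP positions. A window
    with zero control heterozygosity but nonzero case heterozygosity has no
    defined ratio and is emitted as NaN.

    ``zero_mode`` controls fully swept windows (ratio exactly 0): "literal"
    applies the printed formula (value -1); "floor" replaces them with the
    minimum of the other defined normalized values, acknowledging that
    complete case fixation is the strongest possible sweep signal.
    """
    if zero_mode not in ("literal", "floor"):
        raise ValueError("zero_mode must be 'literal' or 'floor'")
    if window_snps < 1:
        raise ValueError("window_snps must be >= 1")
    cols = dataset.snp_indices(chromosome)
    if cols.size < window_snps:
        raise ValueError(
            f"chromosome {chromosome!r} has {cols.size} SNPs, fewer than the "
            f"{window_snps}-SNP window"
        )
    if dataset.case_mask.sum() == 0 or dataset.control_mask.sum() == 0:
        raise ValueError("need both case and control samples")

    het_case = _group_het_rates(dataset, dataset.case_mask, cols)
    het_ctrl = _group_het_rates(dataset, dataset.control_mask, cols)
    pos = dataset.snps["position_bp"].to_numpy()[cols].astype(np.float64)

    n_windows = cols.size - window_snps + 1
    idx = np.arange(n_windows)[:, None] + np.arange(window_snps)[None, :]
    with np.errstate(invalid="ignore"):
        w_case = np.nanmean(het_case[idx], axis=1)
        w_ctrl = np.nanmean(het_ctrl[idx], axis=1)
    mid = pos[idx].mean(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(
            w_ctrl > 0, w_case / np.where(w_ctrl > 0, w_ctrl, 1.0), np.nan
        )
        # both groups zero-heterozygous: no relative signal either way
        ratio = np.where((w_ctrl == 0) & (w_case == 0), np.nan, ratio)
    normalized = normalize_ratio(ratio)

    if zero_mode == "floor":
        zero = ratio == 0
        others = normalized[~zero & ~np.isnan(normalized)]
        if zero.any() and others.size:
            normalized = np.where(zero, others.min(), normalized)

    windows = pd.DataFrame(
        {
            "midpoint_bp": mid,
            "het_cases": w_case,
            "het_controls": w_ctrl,
            "ratio": ratio,
            "normalized": normalized,
        }
    )
    return SweepProfile(chromosome=chromosome, window_snps=window_snps, windows=windows)
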