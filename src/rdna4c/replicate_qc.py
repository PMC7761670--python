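"""Replicate-concordance checks: binned RPKM coverage and correlation.

Coverage is binned genome-wide, RPKM-normalized against the library size of
the non-excluded chromosomes (the viewpoint chromosome is excluded from the
denominator because bait-proximal mapping would otherwise dominate it), and
replicate agreement is summarized by Pearson or Spearman correlation with
optional zero-skipping and outlier removal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from .core import ContactTrack, InsufficientDataError, NormalizationError, ParameterError


@dataclass
class BinnedCoverage:
    """RPKM values in fixed-size bins tiling each chromosome (last bin short)."""

    bin_size_bp: int
    bins: dict[str, np.ndarray]

    def flatten(self, chroms: Iterable[str] | None = None) -> np.ndarray:
        keys = sorted(self.bins) if chroms is None else list(chroms)
        return np.concatenate([self.bins[c] for c in keys]) if keys else np.array([])


def binned_rpkm(
    track: ContactTrack,
    chrom_sizes: Mapping[str, int],
    bin_size_bp: int,
    excluded_chroms: Iterable[str] = ("X",),
) -> BinnedCoverage:
    """Bin read coverage and RPKM-normalize.

    Reads are apportioned to bins by overlap fraction. The per-million
    library size counts only reads on non-excluded chromosomes; excluded
    chromosomes still receive bins so the viewpoint chromosome can be
    inspected, it just does not influence the denominator.
    """
    if bin_size_bp <= 0:
        raise ParameterError("bin_size_bp must be positive")
    excl = set(excluded_chroms)
    total = track.total_reads(exclude_chroms=excl)
    if total <= 0:
        raise NormalizationError(
            "no reads on non-excluded chromosomes; RPKM denominator is zero"
        )
    per_million = total / 1e6
    per_kb = bin_size_bp / 1e3
    bins: dict[str, np.ndarray] = {}
    for chrom, size in chrom_sizes.items():
        n_bins = (size + bin_size_bp - 1) // bin_size_bp
        bins[chrom] = np.zeros(n_bins)
    for rec in track.records:
        iv = rec.interval
        if iv.chrom not in bins:
            continue
        arr = bins[iv.chrom]
        first = iv.start // bin_size_bp
        last = (iv.end - 1) // bin_size_bp
        length = len(iv)
        for b in range(first, min(last, len(arr) - 1) + 1):
            lo = max(iv.start, b * bin_size_bp)
            hi = min(iv.end, (b + 1) * bin_size_bp)
            arr[b] += rec.value * (hi - lo) / length
    for chrom in bins:
        bins[chrom] = bins[chrom] / per_million / per_kb
    return BinnedCoverage(bin_size_bp=bin_size_bp, bins=bins)


def replicate_correlation(
    a: BinnedCoverage,
    b: BinnedCoverage,
    method: str = "pearson",
    skip_zeros: bool = True,
    remove_outliers: bool = True,
    outlier_mads: float = 200.0,
    drop_chroms: Iterable[str] = (),
) -> float:
    """Correlation between two identically binned coverages.

    With ``skip_zeros``, bins where both samples are zero are dropped; with
    ``remove_outliers``, bins where either sample exceeds its own
    median + ``outlier_mads``*MAD are dropped. The coefficient is computed
    on untransformed values (log1p in the upstream tool affects only the
    scatterplot, not the statistic).
    """
    if a.bin_size_bp != b.bin_size_bp or set(a.bins) != set(b.bins):
        raise ParameterError("coverages must share binning and chromosomes")
    if method not in ("pearson", "spearman"):
        raise ParameterError(f"unknown correlation method {method!r}")
    keep_chroms = [c for c in sorted(a.bins) if c not in set(drop_chroms)]
    x = a.flatten(keep_chroms)
    y = b.flatten(keep_chroms)
    if len(x) != len(y):
        raise ParameterError("binnings differ in bin counts")
    mask = np.ones(len(x), dtype=bool)
    if skip_zeros:
        mask &= ~((x == 0) & (y == 0))
    if remove_outliers:
        for v in (x, y):
            med = np.median(v[mask])
            mad = np.median(np.abs(v[mask] - med))
            mask &= v <= med + outlier_mads * mad
    x, y = x[mask], y[mask]
    if len(x) < 3:
        raise InsufficientDataError(
            f"only {len(x)} bins survive filtering; need at least 3"
        )
    if method == "pearson":
        r = stats.pearsonr(x, y).statistic
    else:
        r = stats.spearmanr(x, y).statistic
    return float(r)
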