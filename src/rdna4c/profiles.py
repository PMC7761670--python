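"""Average signal metaprofiles around contact sites.

For each site, signal is averaged within fixed-width bins across a window
centered on the site anchor (midpoint by default). Bins that extend past a
chromosome end, or that have no signal record at all, are missing (NaN) —
not zero — so edge sites do not drag the mean curve down.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import (
    GenomicInterval,
    InsufficientDataError,
    ParameterError,
    SignalTrack,
)


@dataclass
class ProfileMatrix:
    """Sites x bins signal averages with bin offsets relative to the anchor."""

    matrix: np.ndarray  # NaN marks missing bins
    offsets: np.ndarray  # bp offset of each bin start relative to the anchor

    @property
    def mean_curve(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.matrix, axis=0)


def _bin_means(
    starts: np.ndarray,
    ends: np.ndarray,
    values: np.ndarray,
    lo: int,
    hi: int,
    bin_bp: int,
) -> np.ndarray:
    """Signal mean per bin over [lo, hi); NaN where no record covers the bin."""
    n_bins = (hi - lo) // bin_bp
    sums = np.zeros(n_bins)
    covered = np.zeros(n_bins)
    first = int(np.searchsorted(ends, lo, side="right"))
    last = int(np.searchsorted(starts, hi, side="left"))
    for i in range(first, last):
        s = max(int(starts[i]), lo)
        e = min(int(ends[i]), hi)
        b0 = (s - lo) // bin_bp
        b1 = (e - 1 - lo) // bin_bp
        for b in range(b0, b1 + 1):
            blo = max(s, lo + b * bin_bp)
            bhi = min(e, lo + (b + 1) * bin_bp)
            sums[b] += values[i] * (bhi - blo)
            covered[b] += bhi - blo
    out = np.full(n_bins, np.nan)
    has = covered > 0
    out[has] = sums[has] / covered[has]
    return out


def metaprofile(
    signal: SignalTrack,
    sites: Sequence[GenomicInterval],
    window_bp: int = 2000,
    bin_bp: int = 50,
    anchor: str = "midpoint",
    chrom_sizes: Mapping[str, int] | None = None,
) -> ProfileMatrix:
    """Per-site signal profile in ``[anchor - window, anchor + window)``.

    Signal within each covered part of a bin is length-weighted; bins
    outside the chromosome (when ``chrom_sizes`` is given) or without any
    signal record are NaN and excluded from the mean curve.
    """
    if not sites:
        raise InsufficientDataError("metaprofile needs at least one site")
    if window_bp <= 0 or bin_bp <= 0 or (2 * window_bp) % bin_bp != 0:
        raise ParameterError("window must be positive and divisible by bin size")
    if anchor not in ("midpoint", "start"):
        raise ParameterError(f"unknown anchor {anchor!r}")
    by_chrom = signal.by_chrom()
    n_bins = 2 * window_bp // bin_bp
    offsets = np.arange(n_bins) * bin_bp - window_bp
    matrix = np.full((len(sites), n_bins), np.nan)
    for row, site in enumerate(sites):
        center = site.midpoint if anchor == "midpoint" else site.start
        lo = center - window_bp
        hi = center + window_bp
        entry = by_chrom.get(site.chrom)
        if entry is None:
            continue
        clip_lo, clip_hi = lo, hi
        if lo < 0:
            clip_lo = lo + ((-lo + bin_bp - 1) // bin_bp) * bin_bp
        if chrom_sizes is not None and site.chrom in chrom_sizes:
            size = chrom_sizes[site.chrom]
            if hi > size:
                clip_hi = hi - ((hi - size + bin_bp - 1) // bin_bp) * bin_bp
        if clip_lo >= clip_hi:
            continue
        starts, ends, values = entry
        vals = _bin_means(starts, ends, values, clip_lo, clip_hi, bin_bp)
        b0 = (clip_lo - lo) // bin_bp
        matrix[row, b0 : b0 + len(vals)] = vals
    return ProfileMatrix(matrix=matrix, offsets=offsets)
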