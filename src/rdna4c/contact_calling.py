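"""Contact-site calling from replicate 4C coverage tracks.

The calling chain is: intersect the two biological replicates (a read pair
belongs to the same contact if the records overlap by at least one
nucleotide, and the intersected region takes the mean of the two replicate
values), drop records that map entirely inside annotated repeats, keep
records whose mean read count reaches the contact threshold, and extend
each surviving contact by the assay's positional uncertainty (a six-cutter
digest localizes a contact only to about +/-2.5 kb).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import (
    BedGraphRecord,
    ContactTrack,
    GenomicInterval,
    ParameterError,
    RepeatRecord,
)


@dataclass
class PipelineConfig:
    """Every tunable constant of the analysis, with the study defaults.

    ``contact_read_threshold`` and ``gene_read_threshold`` are the 100-read
    cutoffs applied to mean per-contact reads and per-gene totals;
    ``extension_bp`` is the +/-2.5 kb contact resolution; the effective
    genome size and the X-chromosome exclusion parameterize RPKM
    normalization (the 4C bait sits on X, so X inflates library size).
    """

    contact_read_threshold: float = 100
    gene_read_threshold: float = 100
    extension_bp: int = 2500
    min_state_overlap_fraction: float = 0.5
    effective_genome_size: int = 142_573_017
    excluded_normalization_chroms: frozenset[str] = frozenset({"X"})
    bin_size_bp: int = 50
    n_shuffles_states: int = 10_000
    n_shuffles_overlap: int = 100_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.contact_read_threshold <= 0 or self.gene_read_threshold <= 0:
            raise ParameterError("read thresholds must be positive")
        if self.extension_bp < 0:
            raise ParameterError("extension_bp must be >= 0")
        if not 0 < self.min_state_overlap_fraction <= 1:
            raise ParameterError("min_state_overlap_fraction must be in (0, 1]")
        if self.bin_size_bp <= 0:
            raise ParameterError("bin_size_bp must be positive")


def intersect_replicates(rep1: ContactTrack, rep2: ContactTrack) -> ContactTrack:
    """Intersect two replicate tracks, averaging values over overlap regions.

    Every overlapping pair of records (one from each replicate) contributes
    one output record covering exactly their intersection, valued at the
    arithmetic mean of the two replicate values. Records with no partner in
    the other replicate are dropped. Abutting outputs are merged only when
    their values are equal, which keeps the result a valid ContactTrack
    without inventing extra averaging.
    """
    a_by = rep1.by_chrom()
    b_by = rep2.by_chrom()
    out: list[BedGraphRecord] = []
    for chrom in sorted(set(a_by) & set(b_by)):
        s1, e1, v1 = a_by[chrom]
        s2, e2, v2 = b_by[chrom]
        i = j = 0
        pending: tuple[int, int, float] | None = None
        while i < len(s1) and j < len(s2):
            lo = max(s1[i], s2[j])
            hi = min(e1[i], e2[j])
            if lo < hi:
                val = (v1[i] + v2[j]) / 2.0
                if pending is not None and pending[1] == lo and pending[2] == val:
                    pending = (pending[0], int(hi), val)
                else:
                    if pending is not None:
                        out.append(
                            BedGraphRecord(
                                GenomicInterval(chrom, pending[0], pending[1]),
                                pending[2],
                            )
                        )
                    pending = (int(lo), int(hi), val)
            if e1[i] <= e2[j]:
                i += 1
            else:
                j += 1
        if pending is not None:
            out.append(
                BedGraphRecord(
                    GenomicInterval(chrom, pending[0], pending[1]), pending[2]
                )
            )
    sample = f"{rep1.sample_id}&{rep2.sample_id}" if rep1.sample_id else ""
    return ContactTrack(out, sample_id=sample, condition=rep1.condition)


def filter_repeats(
    track: ContactTrack, repeats: Sequence[RepeatRecord]
) -> ContactTrack:
    """Remove records that lie entirely inside a single repeat entry.

    A record survives unless some one repeat interval fully contains it
    (partial overlaps are kept unmodified) — the conservative containment
    rule, equivalent to ``bedtools intersect -v -f 1.0``.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in repeats:
        by_chrom.setdefault(r.interval.chrom, []).append(
            (r.interval.start, r.interval.end)
        )
    # prefix max of repeat ends over repeats sorted by start: a record is
    # contained in some repeat iff max{r.end : r.start <= rec.start} >= rec.end
    index: dict[str, tuple[list[int], np.ndarray]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts = [s for s, _ in ivs]
        ends = np.array([e for _, e in ivs], dtype=np.int64)
        index[chrom] = (starts, np.maximum.accumulate(ends))
    kept = []
    for rec in track.records:
        iv = rec.interval
        idx = index.get(iv.chrom)
        if idx is not None:
            starts, maxend = idx
            k = bisect.bisect_right(starts, iv.start)
            if k > 0 and maxend[k - 1] >= iv.end:
                continue
        kept.append(rec)
    return ContactTrack(kept, sample_id=track.sample_id, condition=track.condition)


def threshold_contacts(track: ContactTrack, threshold: float) -> ContactTrack:
    """Keep records whose value is at least ``threshold`` (inclusive)."""
    if threshold <= 0:
        raise ParameterError("threshold must be positive")
    return ContactTrack(
        [r for r in track.records if r.value >= threshold],
        sample_id=track.sample_id,
        condition=track.condition,
    )


def extend_contacts(
    track: ContactTrack,
    extension_bp: int,
    chrom_sizes: Mapping[str, int],
) -> list[tuple[GenomicInterval, float]]:
    """Extend each contact by ``extension_bp`` on both sides, clamped to the
    chromosome; the result may contain overlapping intervals and is returned
    as plain ``(interval, value)`` pairs rather than a ContactTrack."""
    if extension_bp < 0:
        raise ParameterError("extension_bp must be >= 0")
    out = []
    for rec in track.records:
        iv = rec.interval
        if iv.chrom not in chrom_sizes:
            raise KeyError(f"chromosome {iv.chrom!r} missing from chrom_sizes")
        out.append(
            (
                GenomicInterval(
                    iv.chrom,
                    max(0, iv.start - extension_bp),
                    min(chrom_sizes[iv.chrom], iv.end + extension_bp),
                ),
                rec.value,
            )
        )
    return out
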