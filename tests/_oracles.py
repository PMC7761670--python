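"""Independent brute-force oracles used to check the interval machinery.

Everything here works per base over explicit numpy arrays — deliberately
naive, O(genome length), and structurally unrelated to the sweep/bisect
implementations it validates.
"""

from __future__ import annotations

import numpy as np

from rdna4c.core import (
    BedGraphRecord,
    ContactTrack,
    GenomicInterval,
    RepeatRecord,
    StateAnnotation,
)


def per_base_values(track: ContactTrack, chrom: str, length: int) -> np.ndarray:
    """Array of per-base values; NaN where the track has no record."""
    arr = np.full(length, np.nan)
    for rec in track.records:
        if rec.interval.chrom == chrom:
            arr[rec.interval.start : rec.interval.end] = rec.value
    return arr


def oracle_intersect(
    rep1: ContactTrack, rep2: ContactTrack, chroms: dict[str, int]
) -> dict[str, np.ndarray]:
    """Per-base mean of the two replicates where both are covered."""
    out = {}
    for chrom, length in chroms.items():
        a = per_base_values(rep1, chrom, length)
        b = per_base_values(rep2, chrom, length)
        out[chrom] = (a + b) / 2.0  # NaN wherever either replicate is absent
    return out


def oracle_filter_repeats(
    track: ContactTrack, repeats: list[RepeatRecord]
) -> set[tuple[str, int, int]]:
    """Record keys that survive the full-containment repeat filter."""
    kept = set()
    for rec in track.records:
        iv = rec.interval
        contained = any(
            r.interval.chrom == iv.chrom
            and r.interval.start <= iv.start
            and iv.end <= r.interval.end
            for r in repeats
        )
        if not contained:
            kept.add((iv.chrom, iv.start, iv.end))
    return kept


def oracle_assign(
    extended: list[tuple[GenomicInterval, float]], genes
) -> dict[str, float]:
    """Per-gene totals by quadratic pairwise overlap testing."""
    totals = {g.gene_id: 0.0 for g in genes}
    for iv, value in extended:
        for g in genes:
            gi = g.interval
            if gi.chrom == iv.chrom and gi.start < iv.end and iv.start < gi.end:
                totals[g.gene_id] += value
    return totals


def oracle_state_assign(
    site: GenomicInterval, states: StateAnnotation, frac: float
) -> int | None:
    """Per-base state coverage of the site; fraction rule with tie-break."""
    cover = np.zeros(10, dtype=int)
    for seg in states.segments():
        si = seg.interval
        if si.chrom != site.chrom:
            continue
        lo, hi = max(si.start, site.start), min(si.end, site.end)
        if hi > lo:
            cover[seg.state] += hi - lo
    need = frac * len(site)
    best, best_cov = None, -1
    for st in range(1, 10):
        if cover[st] >= need and cover[st] > best_cov:
            best, best_cov = st, cover[st]
    return best


def random_track(
    rng: np.random.Generator,
    chroms: dict[str, int],
    n_records: int,
    max_value: float = 300.0,
    integer_values: bool = False,
) -> ContactTrack:
    """Random valid track: sorted, disjoint records over the given genome."""
    records = []
    names = sorted(chroms)
    for _ in range(n_records):
        chrom = names[int(rng.integers(len(names)))]
        length = int(rng.integers(20, 400))
        start = int(rng.integers(0, max(1, chroms[chrom] - length)))
        iv = GenomicInterval(chrom, start, start + length)
        if any(iv.overlaps(r.interval) for r in records):
            continue
        value = float(rng.integers(1, int(max_value))) if integer_values else float(
            rng.uniform(0.5, max_value)
        )
        records.append(BedGraphRecord(iv, value))
    return ContactTrack(records)


def random_states(
    rng: np.random.Generator, chroms: dict[str, int], mean_len: int = 3000
) -> StateAnnotation:
    """Random gapless 9-state tiling."""
    from rdna4c.core import StateSegment

    segs = []
    for chrom, size in chroms.items():
        pos = 0
        while pos < size:
            length = int(rng.integers(mean_len // 3, mean_len * 2))
            end = min(pos + length, size)
            segs.append(
                StateSegment(GenomicInterval(chrom, pos, end), int(rng.integers(1, 10)))
            )
            pos = end
    return StateAnnotation(segs)
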