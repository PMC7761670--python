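"""Genomic-feature and chromatin-state annotation of contact sites.

Feature classification follows the midpoint-with-priority convention of
peak annotators: the site midpoint is tested against promoter windows
(strand-aware [TSS-1000, TSS+100)), TTS windows ([TES-100, TES+1000)),
UTRs, exons, gene bodies (intron), then repeats, falling through to
intergenic. Chromatin-state assignment uses the fractional-overlap rule:
a site belongs to a state when at least ``min_overlap_fraction`` of its
length lies in segments of that state (overlap accumulates across segments
of the same state).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    GeneRecord,
    GeneSet,
    GenomicInterval,
    ParameterError,
    RepeatRecord,
    StateAnnotation,
)

FEATURE_CLASSES = (
    "promoter",
    "TTS",
    "utr5",
    "utr3",
    "exon",
    "intron",
    "intergenic",
    "repeat_LTR",
    "repeat_other",
)

PROMOTER_UPSTREAM = 1000
PROMOTER_DOWNSTREAM = 100
TTS_UPSTREAM = 100
TTS_DOWNSTREAM = 1000


def _promoter_window(gene: GeneRecord) -> tuple[int, int]:
    if gene.strand == "+":
        return gene.tss - PROMOTER_UPSTREAM, gene.tss + PROMOTER_DOWNSTREAM
    return gene.tss - PROMOTER_DOWNSTREAM + 1, gene.tss + PROMOTER_UPSTREAM + 1


def _tts_window(gene: GeneRecord) -> tuple[int, int]:
    if gene.strand == "+":
        return gene.tes - TTS_UPSTREAM, gene.tes + TTS_DOWNSTREAM
    return gene.tes - TTS_DOWNSTREAM + 1, gene.tes + TTS_UPSTREAM + 1


def annotate_feature(
    site: GenomicInterval,
    genes: GeneSet,
    repeats: Sequence[RepeatRecord] = (),
) -> str:
    """Classify a site by its midpoint; exactly one class is returned."""
    mid = site.midpoint
    chrom_genes = genes.by_chrom().get(site.chrom, [])
    near = [
        g
        for g in chrom_genes
        if g.interval.start - PROMOTER_UPSTREAM - TTS_DOWNSTREAM
        <= mid
        < g.interval.end + PROMOTER_UPSTREAM + TTS_DOWNSTREAM
    ]
    if any(lo <= mid < hi for g in near for lo, hi in (_promoter_window(g),)):
        return "promoter"
    if any(lo <= mid < hi for g in near for lo, hi in (_tts_window(g),)):
        return "TTS"
    for attr, label in (("utr5", "utr5"), ("utr3", "utr3"), ("exons", "exon")):
        for g in near:
            if any(iv.start <= mid < iv.end for iv in getattr(g, attr)):
                return label
    if any(g.interval.start <= mid < g.interval.end for g in near):
        return "intron"
    hit_classes = {
        r.repeat_class
        for r in repeats
        if r.interval.chrom == site.chrom and r.interval.start <= mid < r.interval.end
    }
    if "LTR" in hit_classes:
        return "repeat_LTR"
    if hit_classes:
        return "repeat_other"
    return "intergenic"


def assign_chromatin_state(
    site: GenomicInterval,
    states: StateAnnotation,
    min_overlap_fraction: float = 0.5,
) -> int | None:
    """State whose segments cover >= ``min_overlap_fraction`` of the site.

    Overlap accumulates across segments sharing a state. If several states
    qualify (possible only at fractions <= 0.5), the larger overlap wins,
    ties going to the lower state label. Returns None when no state
    qualifies.
    """
    if not 0 < min_overlap_fraction <= 1:
        raise ParameterError("min_overlap_fraction must be in (0, 1]")
    arrays = states.arrays().get(site.chrom)
    if arrays is None:
        return None
    starts, ends, labels = arrays
    lo = int(np.searchsorted(ends, site.start, side="right"))
    hi = int(np.searchsorted(starts, site.end, side="left"))
    if lo >= hi:
        return None
    ov = np.minimum(ends[lo:hi], site.end) - np.maximum(starts[lo:hi], site.start)
    ov = np.maximum(ov, 0)
    per_state: dict[int, int] = {}
    for st, o in zip(labels[lo:hi], ov):
        if o > 0:
            per_state[int(st)] = per_state.get(int(st), 0) + int(o)
    need = min_overlap_fraction * len(site)
    qualifying = [(o, -st) for st, o in per_state.items() if o >= need]
    if not qualifying:
        return None
    best = max(qualifying)
    return -best[1]


@dataclass
class StateDistribution:
    """Per-state counts and proportions over the assigned sites."""

    counts: dict[int, int]
    total_sites: int
    unassigned: int

    @property
    def proportions(self) -> dict[int, float]:
        assigned = sum(self.counts.values())
        if assigned == 0:
            return {}
        return {st: c / assigned for st, c in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        props = self.proportions
        return pd.DataFrame(
            {
                "state": sorted(self.counts),
                "count": [self.counts[s] for s in sorted(self.counts)],
                "proportion": [props.get(s, 0.0) for s in sorted(self.counts)],
            }
        )


def state_distribution(
    sites: Sequence[GenomicInterval],
    states: StateAnnotation,
    min_overlap_fraction: float = 0.5,
) -> StateDistribution:
    counts: dict[int, int] = {}
    unassigned = 0
    for site in sites:
        st = assign_chromatin_state(site, states, min_overlap_fraction)
        if st is None:
            unassigned += 1
        else:
            counts[st] = counts.get(st, 0) + 1
    return StateDistribution(counts=counts, total_sites=len(sites), unassigned=unassigned)


def feature_distribution(
    sites: Sequence[GenomicInterval],
    genes: GeneSet,
    repeats: Sequence[RepeatRecord] = (),
) -> pd.DataFrame:
    """Per-class site counts and proportions (Fig-8A-style pie table)."""
    counts = {cls: 0 for cls in FEATURE_CLASSES}
    for site in sites:
        counts[annotate_feature(site, genes, repeats)] += 1
    total = max(len(sites), 1)
    return pd.DataFrame(
        {
            "feature": list(counts),
            "count": list(counts.values()),
            "proportion": [c / total for c in counts.values()],
        }
    )


def per_chromosome_counts(gene_list: Sequence[str], genes: GeneSet) -> pd.DataFrame:
    """How many listed genes fall on each chromosome."""
    chroms = [genes[g].interval.chrom for g in gene_list]
    series = pd.Series(chroms, dtype=str).value_counts().sort_index()
    return series.rename_axis("chrom").reset_index(name="n_genes")
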