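"""Assignment of (extended) contacts to genes and gene-list operations.

A contact contributes its full read value to every gene whose body it
overlaps by at least one base (multi-overlap counting, so one 5 kb extended
contact bridging two genes counts fully toward both). Gene lists are then
selected by a total-reads threshold, compared by exact Venn partitions, and
checked against the viewpoint for near-bait artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GeneSet, GenomicInterval, ParameterError, ValidationError


@dataclass
class GeneContactCounts:
    """Per-gene assigned read totals for one sample."""

    counts: dict[str, float]
    sample_id: str = ""
    condition: str = ""

    def nonzero(self) -> dict[str, float]:
        return {g: v for g, v in self.counts.items() if v > 0}


def assign_contacts_to_genes(
    extended_contacts: Sequence[tuple[GenomicInterval, float]],
    genes: GeneSet,
    sample_id: str = "",
    condition: str = "",
) -> GeneContactCounts:
    """Sum contact read values over every gene body each contact overlaps."""
    by_chrom = genes.by_chrom()
    arrays = {
        chrom: (
            np.array([g.interval.start for g in lst], dtype=np.int64),
            np.array([g.interval.end for g in lst], dtype=np.int64),
            [g.gene_id for g in lst],
        )
        for chrom, lst in by_chrom.items()
    }
    counts = {gid: 0.0 for gid in genes.gene_ids()}
    for iv, value in extended_contacts:
        entry = arrays.get(iv.chrom)
        if entry is None:
            continue
        starts, ends, ids = entry
        hit = np.nonzero((starts < iv.end) & (ends > iv.start))[0]
        for k in hit:
            counts[ids[k]] += value
    return GeneContactCounts(counts=counts, sample_id=sample_id, condition=condition)


def select_contact_genes(
    counts: GeneContactCounts, gene_read_threshold: float
) -> list[str]:
    """Genes with total assigned reads >= threshold, by descending reads then id."""
    if gene_read_threshold <= 0:
        raise ParameterError("gene_read_threshold must be positive")
    hits = [(g, v) for g, v in counts.counts.items() if v >= gene_read_threshold]
    hits.sort(key=lambda t: (-t[1], t[0]))
    return [g for g, _ in hits]


@dataclass
class GeneListComparison:
    """Exact Venn partition of 2 or 3 named gene lists."""

    names: tuple[str, ...]
    regions: dict[tuple[bool, ...], frozenset[str]]

    @property
    def counts(self) -> dict[tuple[bool, ...], int]:
        return {k: len(v) for k, v in self.regions.items()}

    def region(self, *membership: bool) -> frozenset[str]:
        return self.regions[tuple(membership)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key, members in sorted(self.regions.items(), reverse=True):
            label = " & ".join(
                (name if inside else f"not {name}")
                for name, inside in zip(self.names, key)
            )
            rows.append({"region": label, "count": len(members),
                         "members": ",".join(sorted(members))})
        return pd.DataFrame(rows)


def compare_gene_lists(lists: Mapping[str, Sequence[str]]) -> GeneListComparison:
    """Venn partition (counts plus memberships) of 2 or 3 named lists."""
    if not 2 <= len(lists) <= 3:
        raise ParameterError("compare_gene_lists takes 2 or 3 lists")
    names = tuple(lists)
    sets = []
    for name in names:
        lst = list(lists[name])
        if len(lst) != len(set(lst)):
            dupes = sorted({g for g in lst if lst.count(g) > 1})
            raise ValidationError(f"list {name!r} contains duplicates: {dupes[:5]}")
        sets.append(set(lst))
    universe = set().union(*sets)
    regions: dict[tuple[bool, ...], set[str]] = {}
    for item in universe:
        key = tuple(item in s for s in sets)
        regions.setdefault(key, set()).add(item)
    # every non-empty membership pattern is reported, including empty regions
    from itertools import product

    for key in product((True, False), repeat=len(sets)):
        if any(key):
            regions.setdefault(key, set())
    return GeneListComparison(
        names=names, regions={k: frozenset(v) for k, v in regions.items()}
    )


def viewpoint_proximity(
    bait: GenomicInterval,
    genes: GeneSet,
    contact_gene_list: Sequence[str],
) -> pd.DataFrame:
    """Distance from the viewpoint to each contact gene on the bait chromosome.

    Distance is the edge-to-edge gap between the bait interval and the gene
    body (0 when they overlap). Contact genes on other chromosomes appear
    with ``linked=False`` and no distance, since trans-contacts cannot be a
    bait-proximity artefact. Sorted ascending by distance, cis genes first.
    """
    rows = []
    for gid in contact_gene_list:
        g = genes[gid]
        if g.interval.chrom == bait.chrom:
            rows.append(
                {
                    "gene_id": gid,
                    "symbol": g.symbol,
                    "chrom": g.interval.chrom,
                    "linked": True,
                    "distance_bp": bait.distance_to(g.interval),
                }
            )
        else:
            rows.append(
                {
                    "gene_id": gid,
                    "symbol": g.symbol,
                    "chrom": g.interval.chrom,
                    "linked": False,
                    "distance_bp": np.nan,
                }
            )
    frame = pd.DataFrame(
        rows, columns=["gene_id", "symbol", "chrom", "linked", "distance_bp"]
    )
    return frame.sort_values(
        ["linked", "distance_bp", "gene_id"], ascending=[False, True, True]
    ).reset_index(drop=True)
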