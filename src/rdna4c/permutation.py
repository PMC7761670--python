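"""Resampling nulls: gene-list overlap and chromatin-state enrichment.

Two bespoke procedures drive the significance claims of the analysis:

* ``overlap_null`` — how large an overlap two gene lists of size k drawn
  from a universe of N unique names show by chance, estimated by repeated
  Fisher-Yates shuffles (the closed-form reference is the hypergeometric
  distribution, used as an oracle in the tests).
* ``state_enrichment`` — whether contact sites concentrate in particular
  chromatin states, against nulls built by three segmentation-shuffling
  schemes that preserve increasing amounts of the 9-state track structure.

Every routine takes an explicit seed; shuffles consume independent
substreams spawned from it, so results are reproducible and could be
computed in parallel without changing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    GenomicInterval,
    InsufficientDataError,
    ParameterError,
    StateAnnotation,
    ValidationError,
)
from .annotation import assign_chromatin_state

SHUFFLE_SCHEMES = ("label_shuffle", "segment_shuffle", "coord_and_state_shuffle")


@dataclass
class OverlapNullSummary:
    n_shuffles: int
    universe_size: int
    list_size: int
    mean: float
    sd: float
    min: float
    max: float
    observed: float | None = None
    empirical_p: float | None = None


def overlap_null(
    universe: Sequence[str],
    reference: Sequence[str],
    k: int,
    n_shuffles: int,
    seed: int,
    observed: float | None = None,
) -> OverlapNullSummary:
    """Null distribution of the overlap fraction between a fixed reference
    list and the first ``k`` elements of a freshly shuffled universe.

    Each draw Fisher-Yates-shuffles the full universe, takes the first k
    identifiers and records the fraction of them present in the reference.
    If ``observed`` is given, the empirical p-value uses add-one smoothing:
    (1 + #{draws >= observed}) / (n_shuffles + 1).
    """
    ids = list(universe)
    if len(set(ids)) != len(ids):
        raise ValidationError("universe contains duplicate identifiers")
    ref = set(reference)
    if not ref <= set(ids):
        raise ValidationError("reference is not a subset of the universe")
    if not 0 < k <= len(ids):
        raise ParameterError(f"k={k} outside 1..{len(ids)}")
    if n_shuffles < 1:
        raise ParameterError("n_shuffles must be >= 1")
    n = len(ids)
    mask = np.zeros(n, dtype=bool)
    index = {g: i for i, g in enumerate(ids)}
    for g in ref:
        mask[index[g]] = True
    fractions = np.empty(n_shuffles)
    children = np.random.SeedSequence(seed).spawn(n_shuffles)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        perm = rng.permutation(n)
        fractions[i] = mask[perm[:k]].sum() / k
    summary = OverlapNullSummary(
        n_shuffles=n_shuffles,
        universe_size=n,
        list_size=k,
        mean=float(fractions.mean()),
        sd=float(fractions.std(ddof=1)),
        min=float(fractions.min()),
        max=float(fractions.max()),
    )
    if observed is not None:
        summary.observed = float(observed)
        summary.empirical_p = float(
            (1 + int((fractions >= observed).sum())) / (n_shuffles + 1)
        )
    return summary


def _shuffled_arrays(
    states: StateAnnotation, scheme: str, rng: np.random.Generator
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    arrays = states.arrays()
    if scheme == "label_shuffle":
        # coordinates untouched; labels permuted genome-wide
        all_labels = np.concatenate([a[2] for _, a in sorted(arrays.items())])
        perm = rng.permutation(all_labels)
        out = {}
        pos = 0
        for chrom in sorted(arrays):
            starts, ends, labels = arrays[chrom]
            out[chrom] = (starts, ends, perm[pos : pos + len(labels)])
            pos += len(labels)
        return out
    if scheme == "segment_shuffle":
        # per chromosome: reorder (length, label) pairs, rebuild coordinates
        out = {}
        for chrom in sorted(arrays):
            starts, ends, labels = arrays[chrom]
            lengths = ends - starts
            order = rng.permutation(len(lengths))
            new_lengths = lengths[order]
            new_ends = int(starts[0]) + np.cumsum(new_lengths)
            new_starts = new_ends - new_lengths
            out[chrom] = (new_starts, new_ends, labels[order])
        return out
    if scheme == "coord_and_state_shuffle":
        # pool all segments genome-wide, reassign to chromosomes by
        # sequentially filling each chromosome's original total segment length
        chroms = sorted(arrays)
        lengths = np.concatenate([arrays[c][1] - arrays[c][0] for c in chroms])
        labels = np.concatenate([arrays[c][2] for c in chroms])
        order = rng.permutation(len(lengths))
        lengths, labels = lengths[order], labels[order]
        capacities = {c: int((arrays[c][1] - arrays[c][0]).sum()) for c in chroms}
        out = {}
        pos = 0
        for ci, chrom in enumerate(chroms):
            take_len = 0
            take_n = 0
            while pos + take_n < len(lengths) and (
                take_len < capacities[chrom] or ci == len(chroms) - 1
            ):
                take_len += int(lengths[pos + take_n])
                take_n += 1
            chunk_len = lengths[pos : pos + take_n]
            chunk_lab = labels[pos : pos + take_n]
            origin = int(arrays[chrom][0][0])
            new_ends = origin + np.cumsum(chunk_len)
            out[chrom] = (new_ends - chunk_len, new_ends, chunk_lab)
            pos += take_n
        return out
    raise ParameterError(f"unknown shuffle scheme {scheme!r}")


def shuffle_states(
    states: StateAnnotation, scheme: str, seed: int | np.random.Generator
) -> StateAnnotation:
    """One shuffled copy of the segmentation under the named scheme.

    ``label_shuffle`` permutes state labels over fixed segment coordinates;
    ``segment_shuffle`` reorders each chromosome's (length, label) segments
    and rebuilds coordinates cumulatively; ``coord_and_state_shuffle`` pools
    the genome-wide (length, label) multiset and deals it back out
    chromosome by chromosome.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return StateAnnotation.from_arrays(_shuffled_arrays(states, scheme, rng))


def proportions_z_test(p1: float, n1: int, p2: float, n2: int) -> tuple[float, float]:
    """Two-proportion z-test with pooled variance; returns (z, two-sided p)."""
    if n1 <= 0 or n2 <= 0:
        raise ParameterError("sample sizes must be positive")
    pooled = (p1 * n1 + p2 * n2) / (n1 + n2)
    denom = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    if denom <= 0:
        return 0.0, 1.0
    z = (p1 - p2) / np.sqrt(denom)
    return float(z), float(2 * stats.norm.sf(abs(z)))


def _state_counts(
    sites: Sequence[GenomicInterval],
    arrays: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
    min_overlap_fraction: float,
) -> np.ndarray:
    """Counts of sites per state 1..9 against raw segment arrays."""
    counts = np.zeros(10, dtype=np.int64)  # index 0 unused
    ann = StateAnnotation.from_arrays(arrays)
    for site in sites:
        st = assign_chromatin_state(site, ann, min_overlap_fraction)
        if st is not None:
            counts[st] += 1
    return counts


@dataclass
class StateEnrichmentResult:
    scheme: str
    n_shuffles: int
    n_sites: int
    table: pd.DataFrame  # one row per state

    def state_row(self, state: int) -> pd.Series:
        return self.table.set_index("state").loc[state]


def state_enrichment(
    sites: Sequence[GenomicInterval],
    states: StateAnnotation,
    scheme: str,
    n_shuffles: int,
    min_overlap_fraction: float = 0.5,
    seed: int = 0,
) -> StateEnrichmentResult:
    """Empirical enrichment/depletion of sites per chromatin state.

    Observed per-state counts are compared with counts recomputed after each
    of ``n_shuffles`` segmentation shuffles. Per state the result reports
    add-one empirical p-values for enrichment (null count >= observed) and
    depletion (<=), plus a two-proportion z-test pooling all shuffles.
    """
    if scheme not in SHUFFLE_SCHEMES:
        raise ParameterError(f"unknown shuffle scheme {scheme!r}")
    if n_shuffles < 1:
        raise ParameterError("n_shuffles must be >= 1")
    observed = _state_counts(sites, states.arrays(), min_overlap_fraction)
    n_assigned = int(observed.sum())
    if n_assigned == 0:
        raise InsufficientDataError("no site could be assigned a chromatin state")
    n_sites = len(sites)
    null_counts = np.zeros((n_shuffles, 10), dtype=np.int64)
    children = np.random.SeedSequence(seed).spawn(n_shuffles)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        null_counts[i] = _state_counts(
            sites, _shuffled_arrays(states, scheme, rng), min_overlap_fraction
        )
    rows = []
    for st in range(1, 10):
        obs = int(observed[st])
        null = null_counts[:, st]
        p_enrich = (1 + int((null >= obs).sum())) / (n_shuffles + 1)
        p_deplete = (1 + int((null <= obs).sum())) / (n_shuffles + 1)
        p_obs = obs / n_sites
        n_null = n_shuffles * n_sites
        p_null = float(null.sum()) / n_null
        z, p_prop = proportions_z_test(p_obs, n_sites, p_null, n_null)
        rows.append(
            {
                "state": st,
                "observed_count": obs,
                "observed_proportion": p_obs,
                "null_mean_proportion": p_null,
                "null_sd_proportion": float(null.std(ddof=1)) / n_sites,
                "p_enrich": p_enrich,
                "p_deplete": p_deplete,
                "z": z,
                "p_proportions": p_prop,
            }
        )
    return StateEnrichmentResult(
        scheme=scheme,
        n_shuffles=n_shuffles,
        n_sites=n_sites,
        table=pd.DataFrame(rows),
    )
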