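"""Synthetic miniature genome and 4C/RNA-seq observations with planted truth.

The generator emulates the statistical structure the analysis assumes, at
desk scale: a handful of megabase-sized chromosomes plus a short
bait-bearing chromosome whose distal end plays the rDNA cluster; a
non-overlapping gene complement with strands and exons; a Dfam-style
repeat track; a gapless 9-state chromatin segmentation; two
replicate-correlated negative-binomial 4C coverage tracks per condition
over planted contact sites; an RNA-seq count table with planted
differential expression; and deterministic signal tracks with rectangular
bumps at chosen sites.

Planted structure (all recorded in the :class:`TruthManifest`):

* contact genes in five categories — ``retained`` (same contact strength in
  both conditions), ``lost``/``gained`` (contacts present in only one
  condition), and ``up``/``down`` (4-fold contact-strength changes,
  log2FC = +/-2);
* decoy contact sites placed wholly inside repeat entries, which the repeat
  filter must remove;
* a biased fraction of planted sites placed inside segments of one
  "enriched" chromatin state, so enrichment nulls have signal to find.

Replicate concordance arises from a per-site lognormal latent factor shared
by every sample at that site; counts are NB(mean * factor, alpha) with
variance = mu + alpha * mu^2.
"""

from __future__ import annotations

import bisect
import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    BedGraphRecord,
    CapacityError,
    ContactTrack,
    GeneRecord,
    GeneSet,
    GenomicInterval,
    ParameterError,
    RepeatRecord,
    SignalTrack,
    StateAnnotation,
    StateSegment,
)
from .differential import CountsMatrix


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome lengths plus the viewpoint (bait) interval."""

    chromosomes: dict[str, int]
    bait: GenomicInterval
    seed: int = 0

    def __post_init__(self) -> None:
        for name, length in self.chromosomes.items():
            if length <= 0:
                raise ParameterError(f"chromosome {name!r} has non-positive length")
        if self.bait.chrom not in self.chromosomes:
            raise ParameterError("bait chromosome missing from the genome")
        if self.bait.end > self.chromosomes[self.bait.chrom]:
            raise ParameterError("bait extends past its chromosome end")


def default_genome_spec(seed: int = 0) -> GenomeSpec:
    """Four 1-Mb autosome arms plus a 0.3-Mb bait chromosome whose last
    50 kb is the viewpoint (mirroring the rDNA cluster at the X end)."""
    return GenomeSpec(
        chromosomes={
            "chr2L": 1_000_000,
            "chr2R": 1_000_000,
            "chr3L": 1_000_000,
            "chr3R": 1_000_000,
            "X": 300_000,
        },
        bait=GenomicInterval("X", 250_000, 300_000),
        seed=seed,
    )


@dataclass
class ContactParams:
    """Knobs of the 4C track generator (defaults are the study conditions)."""

    n_retained: int = 30
    n_lost: int = 15
    n_gained: int = 15
    n_up: int = 15  # contact strength x4 under heat shock (log2FC = +2)
    n_down: int = 15  # contact strength /4 under heat shock (log2FC = -2)
    site_mean: float = 400.0
    modulated_low: float = 150.0
    modulated_high: float = 600.0
    dispersion: float = 0.02
    latent_sigma: float = 0.5  # sd of the shared per-site lognormal factor
    site_length: int = 150
    min_sites: int = 1
    max_sites: int = 3
    n_background: int = 300
    background_mean: float = 10.0
    n_repeat_decoys: int = 15
    enriched_state: int = 1
    state_bias: float = 0.7  # target fraction of planted sites inside that state

    def __post_init__(self) -> None:
        if self.site_mean <= 0 or self.modulated_low <= 0 or self.modulated_high <= 0:
            raise ParameterError("NB means must be positive")
        if self.dispersion < 0:
            raise ParameterError("NB dispersion must be >= 0")
        if not 1 <= self.enriched_state <= 9:
            raise ParameterError("enriched_state must be in 1..9")
        if not 0 <= self.state_bias <= 1:
            raise ParameterError("state_bias must be in [0, 1]")


CATEGORY_MEANS = {
    # category -> (control multiplier key, heat-shock multiplier key)
    "retained": ("site_mean", "site_mean"),
    "lost": ("site_mean", None),
    "gained": (None, "site_mean"),
    "up": ("modulated_low", "modulated_high"),
    "down": ("modulated_high", "modulated_low"),
}


@dataclass
class ContactGeneTruth:
    gene_id: str
    category: str
    control_mean: float  # per-site NB mean under control
    hs_mean: float  # per-site NB mean under heat shock
    sites: list[GenomicInterval] = field(default_factory=list)

    @property
    def true_log2fc(self) -> float:
        eps = 0.5
        return math.log2((self.hs_mean + eps) / (self.control_mean + eps))

    def total_mean(self, condition: str) -> float:
        per_site = self.control_mean if condition == "control" else self.hs_mean
        return per_site * len(self.sites)


@dataclass
class TruthManifest:
    """Ground truth emitted alongside simulated observations."""

    contact_genes: dict[str, ContactGeneTruth] = field(default_factory=dict)
    repeat_contacts: list[GenomicInterval] = field(default_factory=list)
    de_genes: dict[str, float] = field(default_factory=dict)
    enriched_states: dict[int, float] = field(default_factory=dict)
    seeds: dict[str, int] = field(default_factory=dict)

    def expected_contact_genes(
        self, condition: str, gene_read_threshold: float, margin: float = 2.0
    ) -> set[str]:
        """Genes whose planted total mean in ``condition`` clears the gene
        threshold with headroom ``margin`` — the honest recall denominator
        (a gene whose true mean sits at or below threshold is not a miss)."""
        return {
            gid
            for gid, t in self.contact_genes.items()
            if t.total_mean(condition) >= margin * gene_read_threshold
        }

    def to_json(self, path: str) -> None:
        payload = {
            "contact_genes": {
                gid: {
                    "category": t.category,
                    "control_mean": t.control_mean,
                    "hs_mean": t.hs_mean,
                    "sites": [[s.chrom, s.start, s.end] for s in t.sites],
                }
                for gid, t in self.contact_genes.items()
            },
            "repeat_contacts": [
                [s.chrom, s.start, s.end] for s in self.repeat_contacts
            ],
            "de_genes": self.de_genes,
            "enriched_states": {str(k): v for k, v in self.enriched_states.items()},
            "seeds": self.seeds,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "TruthManifest":
        with open(path) as fh:
            payload = json.load(fh)
        manifest = cls()
        for gid, entry in payload["contact_genes"].items():
            manifest.contact_genes[gid] = ContactGeneTruth(
                gene_id=gid,
                category=entry["category"],
                control_mean=entry["control_mean"],
                hs_mean=entry["hs_mean"],
                sites=[GenomicInterval(c, s, e) for c, s, e in entry["sites"]],
            )
        manifest.repeat_contacts = [
            GenomicInterval(c, s, e) for c, s, e in payload["repeat_contacts"]
        ]
        manifest.de_genes = dict(payload["de_genes"])
        manifest.enriched_states = {
            int(k): v for k, v in payload["enriched_states"].items()
        }
        manifest.seeds = dict(payload["seeds"])
        return manifest


def _allocate(total: int, weights: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of ``total`` items by weights."""
    w = np.asarray(weights, dtype=float)
    raw = total * w / w.sum()
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base))
    for i in order[:rem]:
        base[i] += 1
    return base.tolist()


def simulate_annotation(
    spec: GenomeSpec,
    n_genes: int = 400,
    n_repeats: int = 150,
    seed: int | None = None,
) -> tuple[GeneSet, list[RepeatRecord], StateAnnotation]:
    """Generate non-overlapping genes, a repeat track and a tiling 9-state
    segmentation (segment lengths log-uniform on [1, 10] kb)."""
    if n_genes < 0 or n_repeats < 0:
        raise ParameterError("n_genes and n_repeats must be >= 0")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    chroms = sorted(spec.chromosomes)

    # --- 9-state tiling, no gaps ---
    segments: list[StateSegment] = []
    for chrom in chroms:
        size = spec.chromosomes[chrom]
        pos = 0
        while pos < size:
            length = int(np.exp(rng.uniform(np.log(1_000), np.log(10_000))))
            end = min(pos + length, size)
            segments.append(
                StateSegment(GenomicInterval(chrom, pos, end), int(rng.integers(1, 10)))
            )
            pos = end
    states = StateAnnotation(segments)

    # --- genes: sequential placement with random gaps, bait region kept free ---
    edge = 1_500
    min_gap = 300
    usable = {}
    for chrom in chroms:
        hi = spec.chromosomes[chrom]
        if chrom == spec.bait.chrom:
            hi = min(hi, spec.bait.start - 3_000)
        usable[chrom] = max(0, hi - 2 * edge)
    per_chrom = _allocate(n_genes, [usable[c] for c in chroms])
    genes: list[GeneRecord] = []
    gene_idx = 0
    for chrom, m in zip(chroms, per_chrom):
        if m == 0:
            continue
        lengths = np.exp(rng.uniform(np.log(1_000), np.log(8_000), size=m)).astype(int)
        slack = usable[chrom] - int(lengths.sum()) - (m + 1) * min_gap
        if slack < 0:
            raise CapacityError(
                f"chromosome {chrom} cannot hold {m} genes "
                f"(need {int(lengths.sum()) + (m + 1) * min_gap}, have {usable[chrom]})"
            )
        w = rng.uniform(0.2, 1.0, size=m + 1)
        gaps = (min_gap + slack * w / w.sum()).astype(int)
        pos = edge
        for gi in range(m):
            pos += int(gaps[gi])
            start, end = pos, pos + int(lengths[gi])
            pos = end
            strand = "+" if rng.random() < 0.5 else "-"
            body = GenomicInterval(chrom, start, end)
            n_ex = int(rng.integers(1, 5))
            cuts = np.sort(rng.choice(np.arange(start + 50, end - 50), size=2 * n_ex - 2, replace=False)) if end - start > 200 and n_ex > 1 else np.array([], dtype=int)
            bounds = [start, *cuts.tolist(), end]
            exons = tuple(
                GenomicInterval(chrom, bounds[2 * i], bounds[2 * i + 1])
                for i in range(len(bounds) // 2)
                if bounds[2 * i + 1] > bounds[2 * i]
            )
            utr5 = utr3 = ()
            if end - start > 400:
                head = GenomicInterval(chrom, start, start + 100)
                tail = GenomicInterval(chrom, end - 100, end)
                utr5, utr3 = ((head,), (tail,)) if strand == "+" else ((tail,), (head,))
            gene_idx += 1
            genes.append(
                GeneRecord(
                    gene_id=f"G{gene_idx:05d}",
                    symbol=f"sym{gene_idx}",
                    interval=body,
                    strand=strand,
                    exons=exons,
                    utr5=utr5,
                    utr3=utr3,
                )
            )

    # --- repeats: uniform placement, may overlap genes ---
    classes = np.array(["LTR", "LINE", "SINE", "low_complexity", "other"])
    weights = np.array([0.25, 0.25, 0.2, 0.15, 0.15])
    sizes = np.array([spec.chromosomes[c] for c in chroms], dtype=float)
    repeats: list[RepeatRecord] = []
    for ri in range(n_repeats):
        chrom = chroms[int(rng.choice(len(chroms), p=sizes / sizes.sum()))]
        length = int(np.exp(rng.uniform(np.log(250), np.log(2_000))))
        start = int(rng.integers(0, max(1, spec.chromosomes[chrom] - length)))
        cls = str(rng.choice(classes, p=weights))
        repeats.append(
            RepeatRecord(
                GenomicInterval(chrom, start, start + length),
                family=f"rep_fam_{ri}",
                repeat_class=cls,
            )
        )
    return GeneSet(genes), repeats, states


class _Occupied:
    """Per-chromosome interval registry rejecting overlapping insertions."""

    def __init__(self) -> None:
        self._by_chrom: dict[str, list[tuple[int, int]]] = {}

    def try_add(self, iv: GenomicInterval) -> bool:
        lst = self._by_chrom.setdefault(iv.chrom, [])
        k = bisect.bisect_left(lst, (iv.start, iv.end))
        if k > 0 and lst[k - 1][1] > iv.start:
            return False
        if k < len(lst) and lst[k][0] < iv.end:
            return False
        lst.insert(k, (iv.start, iv.end))
        return True


def _inside_any_repeat(iv: GenomicInterval, repeats: Sequence[RepeatRecord]) -> bool:
    return any(r.interval.contains(iv) for r in repeats)


def _state_windows(
    window: tuple[str, int, int],
    states: StateAnnotation,
    state: int,
    site_length: int,
) -> list[tuple[int, int]]:
    """Start-position ranges inside ``window`` where a site of
    ``site_length`` fits wholly within a segment of ``state``."""
    chrom, lo, hi = window
    arrays = states.arrays().get(chrom)
    if arrays is None:
        return []
    starts, ends, labels = arrays
    out = []
    for s, e, st in zip(starts, ends, labels):
        if st != state or e <= lo or s >= hi:
            continue
        a = max(int(s), lo)
        b = min(int(e), hi) - site_length
        if b > a:
            out.append((a, b))
    return out


def _nb_draw(rng: np.random.Generator, mean: float, alpha: float) -> int:
    if mean <= 0:
        return 0
    if alpha == 0:
        return int(rng.poisson(mean))
    r = 1.0 / alpha
    p = r / (r + mean)
    return int(rng.negative_binomial(r, p))


def simulate_contact_tracks(
    spec: GenomeSpec,
    genes: GeneSet,
    repeats: Sequence[RepeatRecord],
    states: StateAnnotation,
    params: ContactParams | None = None,
    seed: int | None = None,
) -> tuple[dict[str, ContactTrack], TruthManifest]:
    """Simulate 2 conditions x 2 replicates of 4C coverage plus ground truth.

    Returns a dict keyed ``control_rep1``, ``control_rep2``, ``hs_rep1``,
    ``hs_rep2``. Planted contact genes receive 1-3 sites within the
    +/-2.5 kb assignment reach of the gene body; decoy sites sit wholly
    inside repeat entries; sparse sub-threshold background covers the rest
    of the genome.
    """
    params = params or ContactParams()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    manifest = TruthManifest(seeds={"contacts": spec.seed if seed is None else seed})
    occupied = _Occupied()
    reach = 2_500 - params.site_length  # site fully assignable to its gene

    # order candidate genes: enriched-state availability first, then the rest
    all_genes = list(genes)
    rng.shuffle(all_genes)
    windows = {}
    available, rest = [], []
    for g in all_genes:
        lo = max(0, g.interval.start - reach)
        hi = min(spec.chromosomes[g.interval.chrom], g.interval.end + reach)
        windows[g.gene_id] = (g.interval.chrom, lo, hi)
        if _state_windows(
            windows[g.gene_id], states, params.enriched_state, params.site_length + 10
        ):
            available.append(g)
        else:
            rest.append(g)
    candidates = available + rest
    n_planted = (
        params.n_retained + params.n_lost + params.n_gained + params.n_up + params.n_down
    )
    if n_planted > len(candidates):
        raise CapacityError(
            f"requested {n_planted} contact genes but only {len(candidates)} genes exist"
        )
    categories = (
        ["retained"] * params.n_retained
        + ["lost"] * params.n_lost
        + ["gained"] * params.n_gained
        + ["up"] * params.n_up
        + ["down"] * params.n_down
    )
    rng.shuffle(categories)

    def mean_of(key: str | None) -> float:
        return 0.0 if key is None else float(getattr(params, key))

    site_entries: list[tuple[GenomicInterval, float, float]] = []  # iv, ctrl, hs
    planted_sites: list[GenomicInterval] = []
    for g, cat in zip(candidates, categories):
        ctrl_key, hs_key = CATEGORY_MEANS[cat]
        truth = ContactGeneTruth(
            gene_id=g.gene_id,
            category=cat,
            control_mean=mean_of(ctrl_key),
            hs_mean=mean_of(hs_key),
        )
        n_sites = int(rng.integers(params.min_sites, params.max_sites + 1))
        chrom, lo, hi = windows[g.gene_id]
        biased_ranges = _state_windows(
            windows[g.gene_id], states, params.enriched_state, params.site_length + 10
        )
        for _ in range(n_sites):
            placed = None
            for _attempt in range(60):
                use_bias = biased_ranges and rng.random() < params.state_bias
                if use_bias:
                    a, b = biased_ranges[int(rng.integers(len(biased_ranges)))]
                    start = int(rng.integers(a, b + 1))
                else:
                    start = int(rng.integers(lo, hi - params.site_length))
                iv = GenomicInterval(chrom, start, start + params.site_length)
                if _inside_any_repeat(iv, repeats):
                    continue
                if occupied.try_add(iv):
                    placed = iv
                    break
            if placed is not None:
                truth.sites.append(placed)
                planted_sites.append(placed)
                site_entries.append((placed, truth.control_mean, truth.hs_mean))
        if truth.sites:
            manifest.contact_genes[g.gene_id] = truth

    # --- repeat-contained decoys ---
    big_repeats = [
        r for r in repeats if len(r.interval) >= params.site_length + 4
    ]
    rng.shuffle(big_repeats)
    for r in big_repeats:
        if len(manifest.repeat_contacts) >= params.n_repeat_decoys:
            break
        lo_d = r.interval.start + 1
        hi_d = r.interval.end - 1 - params.site_length
        if hi_d <= lo_d:
            continue
        start = int(rng.integers(lo_d, hi_d + 1))
        iv = GenomicInterval(r.interval.chrom, start, start + params.site_length)
        if occupied.try_add(iv):
            manifest.repeat_contacts.append(iv)
            site_entries.append((iv, params.site_mean, params.site_mean))

    # --- sparse sub-threshold background ---
    chroms = sorted(spec.chromosomes)
    sizes = np.array([spec.chromosomes[c] for c in chroms], dtype=float)
    placed_bg = 0
    while placed_bg < params.n_background:
        chrom = chroms[int(rng.choice(len(chroms), p=sizes / sizes.sum()))]
        start = int(rng.integers(0, spec.chromosomes[chrom] - params.site_length))
        iv = GenomicInterval(chrom, start, start + params.site_length)
        if occupied.try_add(iv):
            site_entries.append((iv, params.background_mean, params.background_mean))
            placed_bg += 1

    # --- draw counts: shared lognormal latent factor, NB per sample ---
    sigma = params.latent_sigma
    samples = {
        "control_rep1": ("control", 0),
        "control_rep2": ("control", 1),
        "hs_rep1": ("heat_shock", 0),
        "hs_rep2": ("heat_shock", 1),
    }
    records: dict[str, list[BedGraphRecord]] = {s: [] for s in samples}
    for iv, ctrl_mean, hs_mean in site_entries:
        latent = float(np.exp(rng.normal(-0.5 * sigma**2, sigma))) if sigma > 0 else 1.0
        for sample, (condition, _rep) in samples.items():
            mean = (ctrl_mean if condition == "control" else hs_mean) * latent
            count = _nb_draw(rng, mean, params.dispersion)
            if count > 0:
                records[sample].append(BedGraphRecord(iv, float(count)))
    tracks = {
        sample: ContactTrack(recs, sample_id=sample, condition=samples[sample][0])
        for sample, recs in records.items()
    }

    # realized enrichment truth: midpoint state of every planted gene site
    state_counts: dict[int, int] = {}
    from .annotation import assign_chromatin_state

    for iv in planted_sites:
        st = assign_chromatin_state(iv, states, 0.5)
        if st is not None:
            state_counts[st] = state_counts.get(st, 0) + 1
    total = sum(state_counts.values())
    if total:
        manifest.enriched_states = {
            st: c / total for st, c in sorted(state_counts.items())
        }
    return tracks, manifest


@dataclass
class ExpressionParams:
    """RNA-seq count generator settings."""

    dispersion: float = 0.05
    base_mean_low: float = 100.0
    base_mean_high: float = 1_000.0

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ParameterError("dispersion must be >= 0")


def simulate_expression_counts(
    genes: GeneSet | Sequence[str],
    de_spec: Mapping[str, float],
    n_reps: int = 2,
    library_sizes: Sequence[float] | None = None,
    params: ExpressionParams | None = None,
    seed: int = 0,
    manifest: TruthManifest | None = None,
) -> tuple[CountsMatrix, TruthManifest]:
    """NB gene-level counts for 2 conditions with planted log2 fold changes.

    ``de_spec`` maps gene ids to their true log2FC (heat shock over
    control); all other genes are null. Per-sample library-size multipliers
    default to 1. Records the truth into ``manifest.de_genes``.
    """
    params = params or ExpressionParams()
    gene_ids = (
        [g.gene_id for g in genes] if isinstance(genes, GeneSet) else list(genes)
    )
    unknown = set(de_spec) - set(gene_ids)
    if unknown:
        raise ParameterError(f"de_spec names unknown genes: {sorted(unknown)[:5]}")
    if n_reps < 1:
        raise ParameterError("n_reps must be >= 1")
    n_samples = 2 * n_reps
    lib = np.ones(n_samples) if library_sizes is None else np.asarray(
        library_sizes, dtype=float
    )
    if len(lib) != n_samples:
        raise ParameterError(f"need {n_samples} library sizes, got {len(lib)}")
    rng = np.random.default_rng(seed)
    sample_ids = [f"rna_control_rep{i + 1}" for i in range(n_reps)] + [
        f"rna_hs_rep{i + 1}" for i in range(n_reps)
    ]
    conditions = {
        s: ("control" if s.startswith("rna_control") else "heat_shock")
        for s in sample_ids
    }
    base = np.exp(
        rng.uniform(
            np.log(params.base_mean_low), np.log(params.base_mean_high), len(gene_ids)
        )
    )
    mat = np.zeros((len(gene_ids), n_samples), dtype=np.int64)
    for gi, gid in enumerate(gene_ids):
        lfc = float(de_spec.get(gid, 0.0))
        for sj, sid in enumerate(sample_ids):
            mean = base[gi] * lib[sj]
            if conditions[sid] == "heat_shock":
                mean *= 2.0**lfc
            mat[gi, sj] = _nb_draw(rng, mean, params.dispersion)
    counts = CountsMatrix(
        counts=pd.DataFrame(mat, index=gene_ids, columns=sample_ids),
        conditions=conditions,
    )
    manifest = manifest or TruthManifest()
    manifest.de_genes = dict(de_spec)
    manifest.seeds["expression"] = seed
    return counts, manifest


def simulate_signal_track(
    spec: GenomeSpec,
    sites: Sequence[GenomicInterval],
    baseline: float = 1.0,
    bump_height: float = 5.0,
    bump_width: int = 500,
    name: str = "signal",
) -> SignalTrack:
    """Deterministic piecewise-constant signal: a flat baseline plus one
    rectangular bump of ``bump_height`` x ``bump_width`` centered at each
    site midpoint; overlapping bumps add."""
    if bump_width <= 0:
        raise ParameterError("bump_width must be positive")
    events: dict[str, list[tuple[int, float]]] = {
        chrom: [] for chrom in spec.chromosomes
    }
    for site in sites:
        if site.chrom not in events:
            raise ParameterError(f"site chromosome {site.chrom!r} not in genome")
        size = spec.chromosomes[site.chrom]
        lo = max(0, site.midpoint - bump_width // 2)
        hi = min(size, lo + bump_width)
        events[site.chrom].append((lo, +bump_height))
        events[site.chrom].append((hi, -bump_height))
    records: list[BedGraphRecord] = []
    for chrom in sorted(spec.chromosomes):
        size = spec.chromosomes[chrom]
        pts = sorted(events[chrom])
        breaks = sorted({0, size, *(p for p, _ in pts)})
        level = baseline
        deltas: dict[int, float] = {}
        for p, d in pts:
            deltas[p] = deltas.get(p, 0.0) + d
        for a, b in zip(breaks, breaks[1:]):
            level += deltas.get(a, 0.0)
            if b > a:
                records.append(BedGraphRecord(GenomicInterval(chrom, a, b), level))
    return SignalTrack(records, name=name)
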