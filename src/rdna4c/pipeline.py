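"""End-to-end orchestration of the contact analysis on one input set.

``run_pipeline`` composes the stages in the study's order — replicate
intersection, repeat filtering, read-count thresholding, contact extension,
gene assignment and selection, differential contact and expression
analysis, feature/state annotation, the enrichment and overlap nulls, the
viewpoint proximity check and signal metaprofiles — writing every stage
output under one directory together with a run manifest (config snapshot,
input checksums, per-stage record counts, seeds).
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .annotation import feature_distribution, per_chromosome_counts, state_distribution
from .contact_calling import (
    PipelineConfig,
    extend_contacts,
    filter_repeats,
    intersect_replicates,
    threshold_contacts,
)
from .core import ContactTrack, GenomicInterval, RepeatRecord, StateAnnotation
from .differential import (
    CountsMatrix,
    round_half_up,
    run_differential,
    volcano_counts,
    volcano_table,
)
from .gene_quantification import (
    assign_contacts_to_genes,
    compare_gene_lists,
    select_contact_genes,
    viewpoint_proximity,
)
from .io_formats import (
    read_bedgraph,
    read_gene_annotation,
    read_repeats_bed,
    read_state_gff,
    write_bedgraph,
    write_gene_annotation,
    write_repeats_bed,
    write_state_gff,
)
from .permutation import overlap_null, state_enrichment
from .profiles import metaprofile
from .replicate_qc import binned_rpkm, replicate_correlation
from .synthetic import (
    ContactParams,
    GenomeSpec,
    TruthManifest,
    default_genome_spec,
    simulate_annotation,
    simulate_contact_tracks,
    simulate_expression_counts,
    simulate_signal_track,
)

CONDITIONS = ("control", "heat_shock")
SAMPLE_KEYS = ("control_rep1", "control_rep2", "hs_rep1", "hs_rep2")


@dataclass
class RunManifest:
    config: dict
    seeds: dict[str, int]
    input_checksums: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, int] = field(default_factory=dict)
    version: str = __version__

    def record(self, stage: str, count: int) -> None:
        if stage in self.stage_counts:
            raise ValueError(f"stage {stage!r} recorded twice")
        self.stage_counts[stage] = int(count)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def simulate_inputs(
    outdir: str,
    seed: int = 0,
    n_genes: int = 400,
    n_repeats: int = 150,
    contact_params: ContactParams | None = None,
    n_de_expression: int = 30,
) -> dict[str, str]:
    """Generate the default synthetic preset and write it as standard files.

    Emits genes (GTF), repeats (BED), chromatin states (GFF3), four 4C
    bedGraphs, an RNA-seq count TSV, a signal bedGraph and the truth
    manifest (JSON). Returns the path map.
    """
    os.makedirs(outdir, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    s_ann, s_tracks, s_expr = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3))
    spec = default_genome_spec(seed=s_ann)
    genes, repeats, states = simulate_annotation(
        spec, n_genes=n_genes, n_repeats=n_repeats, seed=s_ann
    )
    tracks, manifest = simulate_contact_tracks(
        spec, genes, repeats, states, params=contact_params, seed=s_tracks
    )
    # expression: plant DE on a subset of the planted contact genes
    rng = np.random.default_rng(s_expr)
    contact_ids = sorted(manifest.contact_genes)
    de_ids = rng.choice(
        contact_ids, size=min(n_de_expression, len(contact_ids)), replace=False
    )
    de_spec = {
        gid: float(rng.choice([-2.0, 2.0])) for gid in sorted(de_ids)
    }
    expr_counts, manifest = simulate_expression_counts(
        genes, de_spec, n_reps=2, seed=s_expr, manifest=manifest
    )
    signal_sites = [
        iv for t in manifest.contact_genes.values() for iv in t.sites
    ]
    signal = simulate_signal_track(spec, signal_sites, baseline=1.0, bump_height=5.0)

    paths = {}
    paths["genes"] = os.path.join(outdir, "genes.gtf")
    write_gene_annotation(genes, paths["genes"])
    paths["repeats"] = os.path.join(outdir, "repeats.bed")
    write_repeats_bed(repeats, paths["repeats"])
    paths["states"] = os.path.join(outdir, "states.gff3")
    write_state_gff(states, paths["states"])
    for key in SAMPLE_KEYS:
        paths[key] = os.path.join(outdir, f"{key}.bedGraph")
        write_bedgraph(tracks[key], paths[key])
    paths["expression"] = os.path.join(outdir, "expression_counts.tsv")
    expr_counts.counts.rename_axis("gene_id").to_csv(paths["expression"], sep="\t")
    paths["signal"] = os.path.join(outdir, "signal.bedGraph")
    write_bedgraph(signal, paths["signal"])
    paths["truth"] = os.path.join(outdir, "truth_manifest.json")
    manifest.to_json(paths["truth"])
    paths["genome"] = os.path.join(outdir, "genome.json")
    with open(paths["genome"], "w") as fh:
        json.dump(
            {
                "chromosomes": spec.chromosomes,
                "bait": [spec.bait.chrom, spec.bait.start, spec.bait.end],
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    return paths


def load_genome(path: str) -> tuple[dict[str, int], GenomicInterval]:
    with open(path) as fh:
        payload = json.load(fh)
    bait = GenomicInterval(*payload["bait"][:1], *map(int, payload["bait"][1:]))
    return {k: int(v) for k, v in payload["chromosomes"].items()}, bait


def call_contacts(
    rep1: ContactTrack,
    rep2: ContactTrack,
    repeats: Sequence[RepeatRecord],
    chrom_sizes: Mapping[str, int],
    config: PipelineConfig,
    manifest: RunManifest | None = None,
    label: str = "",
) -> tuple[ContactTrack, list[tuple[GenomicInterval, float]]]:
    """intersect -> repeat-filter -> threshold -> extend for one condition."""
    prefix = f"{label}." if label else ""
    intersected = intersect_replicates(rep1, rep2)
    filtered = filter_repeats(intersected, repeats)
    thresholded = threshold_contacts(filtered, config.contact_read_threshold)
    extended = extend_contacts(thresholded, config.extension_bp, chrom_sizes)
    if manifest is not None:
        manifest.record(f"{prefix}intersected", len(intersected))
        manifest.record(f"{prefix}repeat_filtered", len(filtered))
        manifest.record(f"{prefix}thresholded", len(thresholded))
    return thresholded, extended


def quantify_replicates(
    tracks: Mapping[str, ContactTrack],
    repeats: Sequence[RepeatRecord],
    chrom_sizes: Mapping[str, int],
    genes,
    config: PipelineConfig,
) -> CountsMatrix:
    """Per-replicate gene contact counts (repeat-filtered, unthresholded,
    extended), rounded half-up into an integer counts matrix."""
    columns = {}
    conditions = {}
    for key in SAMPLE_KEYS:
        track = filter_repeats(tracks[key], repeats)
        extended = extend_contacts(track, config.extension_bp, chrom_sizes)
        gc = assign_contacts_to_genes(extended, genes, sample_id=key)
        columns[key] = gc.counts
        conditions[key] = tracks[key].condition
    frame = pd.DataFrame(columns)
    frame = frame.loc[(frame.sum(axis=1) > 0)]
    frame = pd.DataFrame(
        round_half_up(frame), index=frame.index, columns=frame.columns
    )
    return CountsMatrix(counts=frame, conditions=conditions)


def run_pipeline(
    outdir: str,
    config: PipelineConfig | None = None,
    inputs: Mapping[str, str] | None = None,
    simulate: bool = False,
    seed: int = 0,
) -> RunManifest:
    """Run every analysis stage; see module docstring. With ``simulate``,
    inputs are generated under ``outdir/inputs`` first. Identical config and
    seed give byte-identical outputs."""
    config = config or PipelineConfig(rng_seed=seed)
    os.makedirs(outdir, exist_ok=True)
    if simulate:
        inputs = simulate_inputs(os.path.join(outdir, "inputs"), seed=seed)
    if inputs is None:
        raise ValueError("either pass input paths or set simulate=True")
    required = ("genes", "repeats", "states", "genome", *SAMPLE_KEYS)
    missing = [k for k in required if k not in inputs]
    if missing:
        raise FileNotFoundError(f"missing inputs: {missing}")
    manifest = RunManifest(
        config={k: sorted(v) if isinstance(v, frozenset) else v
                for k, v in asdict(config).items()},
        seeds={"master": seed},
        input_checksums={k: _sha256(p) for k, p in sorted(inputs.items())},
    )
    chrom_sizes, bait = load_genome(inputs["genome"])
    genes = read_gene_annotation(inputs["genes"], dialect="gtf")
    repeats = read_repeats_bed(inputs["repeats"])
    states = read_state_gff(inputs["states"])
    tracks = {
        key: read_bedgraph(
            inputs[key],
            sample_id=key,
            condition="control" if key.startswith("control") else "heat_shock",
        )
        for key in SAMPLE_KEYS
    }
    for key in SAMPLE_KEYS:
        manifest.record(f"input.{key}", len(tracks[key]))

    # --- replicate QC ---
    qc_rows = []
    for cond, (r1, r2) in {
        "control": ("control_rep1", "control_rep2"),
        "heat_shock": ("hs_rep1", "hs_rep2"),
    }.items():
        cov1 = binned_rpkm(
            tracks[r1], chrom_sizes, config.bin_size_bp,
            config.excluded_normalization_chroms,
        )
        cov2 = binned_rpkm(
            tracks[r2], chrom_sizes, config.bin_size_bp,
            config.excluded_normalization_chroms,
        )
        for method in ("pearson", "spearman"):
            qc_rows.append(
                {
                    "condition": cond,
                    "method": method,
                    "r": replicate_correlation(cov1, cov2, method=method),
                }
            )
    pd.DataFrame(qc_rows).to_csv(
        os.path.join(outdir, "replicate_qc.tsv"), sep="\t", index=False
    )

    # --- contact calling per condition ---
    called = {}
    extended = {}
    for cond, (r1, r2) in {
        "control": ("control_rep1", "control_rep2"),
        "heat_shock": ("hs_rep1", "hs_rep2"),
    }.items():
        thr, ext = call_contacts(
            tracks[r1], tracks[r2], repeats, chrom_sizes, config,
            manifest=manifest, label=cond,
        )
        called[cond] = thr
        extended[cond] = ext
        write_bedgraph(thr, os.path.join(outdir, f"contacts_{cond}.bedGraph"))

    # --- gene lists ---
    gene_lists = {}
    for cond in CONDITIONS:
        gc = assign_contacts_to_genes(extended[cond], genes, condition=cond)
        gene_lists[cond] = select_contact_genes(gc, config.gene_read_threshold)
        manifest.record(f"{cond}.contact_genes", len(gene_lists[cond]))
        pd.Series(gene_lists[cond], name="gene_id").to_csv(
            os.path.join(outdir, f"contact_genes_{cond}.tsv"), sep="\t", index=False
        )
    venn = compare_gene_lists(
        {"control": gene_lists["control"], "heat_shock": gene_lists["heat_shock"]}
    )
    venn.to_frame().to_csv(os.path.join(outdir, "venn.tsv"), sep="\t", index=False)
    union_list = sorted(set(gene_lists["control"]) | set(gene_lists["heat_shock"]))

    # --- viewpoint proximity ---
    vp = viewpoint_proximity(bait, genes, union_list)
    vp.to_csv(os.path.join(outdir, "viewpoint_proximity.tsv"), sep="\t", index=False)

    # --- differential contacts ---
    contact_counts = quantify_replicates(tracks, repeats, chrom_sizes, genes, config)
    diff_contacts = run_differential(contact_counts, baseline="control")
    diff_contacts.to_csv(os.path.join(outdir, "differential_contacts.tsv"), sep="\t")
    vt = volcano_table(diff_contacts)
    manifest.record("diff_contacts.up", volcano_counts(vt)["up"])
    manifest.record("diff_contacts.down", volcano_counts(vt)["down"])

    # --- differential expression restricted to the contact-gene list ---
    if "expression" in inputs:
        expr = pd.read_csv(inputs["expression"], sep="\t", index_col=0)
        keep = [g for g in expr.index if g in set(union_list)]
        if len(keep) >= 1:
            conditions = {
                c: ("control" if "control" in c else "heat_shock")
                for c in expr.columns
            }
            expr_counts = CountsMatrix(counts=expr.loc[keep], conditions=conditions)
            diff_expr = run_differential(expr_counts, baseline="control")
            diff_expr.to_csv(
                os.path.join(outdir, "differential_expression.tsv"), sep="\t"
            )
            vt_e = volcano_table(diff_expr)
            manifest.record("diff_expression.up", volcano_counts(vt_e)["up"])
            manifest.record("diff_expression.down", volcano_counts(vt_e)["down"])

    # --- annotation of contact sites (control condition, Fig-8 style) ---
    sites = [r.interval for r in called["control"].records]
    feature_distribution(sites, genes, repeats).to_csv(
        os.path.join(outdir, "feature_distribution.tsv"), sep="\t", index=False
    )
    state_distribution(sites, states, config.min_state_overlap_fraction).to_frame().to_csv(
        os.path.join(outdir, "state_distribution.tsv"), sep="\t", index=False
    )
    per_chromosome_counts(union_list, genes).to_csv(
        os.path.join(outdir, "genes_per_chromosome.tsv"), sep="\t", index=False
    )

    # --- state-enrichment nulls, three schemes ---
    enrich_frames = []
    for scheme in ("label_shuffle", "segment_shuffle", "coord_and_state_shuffle"):
        res = state_enrichment(
            sites,
            states,
            scheme=scheme,
            n_shuffles=config.n_shuffles_states,
            min_overlap_fraction=config.min_state_overlap_fraction,
            seed=seed + 1,
        )
        frame = res.table.copy()
        frame.insert(0, "scheme", scheme)
        enrich_frames.append(frame)
    pd.concat(enrich_frames).to_csv(
        os.path.join(outdir, "state_enrichment.tsv"), sep="\t", index=False
    )

    # --- overlap null ---
    universe = genes.gene_ids()
    k = max(len(gene_lists["control"]), 1)
    summary = overlap_null(
        universe,
        reference=gene_lists["control"] or universe[:k],
        k=k,
        n_shuffles=config.n_shuffles_overlap,
        seed=seed + 2,
    )
    pd.DataFrame([summary.__dict__]).to_csv(
        os.path.join(outdir, "overlap_null.tsv"), sep="\t", index=False
    )

    # --- metaprofile of the signal track around control contact sites ---
    if "signal" in inputs and sites:
        signal = read_bedgraph(inputs["signal"])
        from .core import SignalTrack

        profile = metaprofile(
            SignalTrack(signal.records), sites, window_bp=2000, bin_bp=50,
            chrom_sizes=chrom_sizes,
        )
        pd.DataFrame(
            {"offset_bp": profile.offsets, "mean_signal": profile.mean_curve}
        ).to_csv(os.path.join(outdir, "metaprofile.tsv"), sep="\t", index=False)

    manifest.to_json(os.path.join(outdir, "run_manifest.json"))
    return manifest
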