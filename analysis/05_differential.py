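"""Differential contact and expression analysis between conditions.

Per-replicate gene contact counts (repeat-filtered, unthresholded,
extended) feed the NB Wald test; expression counts are first restricted to
the contact-gene list, mirroring how the study tests transcription of
rDNA-contacting genes. Planted 4-fold contact changes are scored for sign
and significance against the truth manifest.
"""

import json
from pathlib import Path

import pandas as pd

from rdna4c import (
    CountsMatrix,
    PipelineConfig,
    TruthManifest,
    run_differential,
    volcano_counts,
    volcano_table,
)
from rdna4c.io_formats import read_bedgraph, read_gene_annotation, read_repeats_bed
from rdna4c.pipeline import SAMPLE_KEYS, load_genome, quantify_replicates

RESULTS = Path("results")


def main() -> None:
    paths = json.loads((RESULTS / "paths.json").read_text())
    chrom_sizes, _ = load_genome(paths["genome"])
    genes = read_gene_annotation(paths["genes"])
    repeats = read_repeats_bed(paths["repeats"])
    manifest = TruthManifest.from_json(paths["truth"])
    tracks = {
        key: read_bedgraph(
            paths[key],
            sample_id=key,
            condition="control" if key.startswith("control") else "heat_shock",
        )
        for key in SAMPLE_KEYS
    }
    counts = quantify_replicates(tracks, repeats, chrom_sizes, genes, PipelineConfig())
    contacts = run_differential(counts, baseline="control")
    contacts.to_csv(RESULTS / "differential_contacts.tsv", sep="\t")
    vc = volcano_counts(volcano_table(contacts))
    print(f"contacts: {vc['up']} genes gain, {vc['down']} lose (padj<0.05, |lfc|>1)")

    modulated = {
        g: t for g, t in manifest.contact_genes.items() if t.category in ("up", "down")
    }
    hits = sum(
        1
        for g, t in modulated.items()
        if g in contacts.index
        and contacts.loc[g, "padj"] < 0.05
        and (contacts.loc[g, "log2fc"] > 0) == (t.category == "up")
    )
    print(
        f"planted |log2FC|=2 contact changes called with correct sign: "
        f"{hits}/{len(modulated)}"
    )

    expr = pd.read_csv(paths["expression"], sep="\t", index_col=0)
    contact_list = set(
        pd.read_csv(RESULTS / "contact_genes_control.tsv", sep="\t")["gene_id"]
    ) | set(
        pd.read_csv(RESULTS / "contact_genes_heat_shock.tsv", sep="\t")["gene_id"]
    )
    keep = [g for g in expr.index if g in contact_list]
    cm = CountsMatrix(
        counts=expr.loc[keep],
        conditions={
            c: ("control" if "control" in c else "heat_shock") for c in expr.columns
        },
    )
    de = run_differential(cm, baseline="control")
    de.to_csv(RESULTS / "differential_expression.tsv", sep="\t")
    ve = volcano_counts(volcano_table(de))
    print(
        f"expression (restricted to {len(keep)} contact genes): "
        f"{ve['up']} up, {ve['down']} down"
    )


if __name__ == "__main__":
    main()
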