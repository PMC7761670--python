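"""Build contact-gene lists, compare them, and check viewpoint proximity.

Extended contacts are assigned to every gene body they overlap; genes with
>= 100 assigned reads form the per-condition contact list. The two lists
are compared as a Venn partition (retained / lost / gained contacts), and
the distance from the viewpoint to each contact gene on the bait
chromosome verifies that near-bait cis-interactions do not drive the lists.
"""

import json
from pathlib import Path

import pandas as pd

from rdna4c import (
    PipelineConfig,
    TruthManifest,
    assign_contacts_to_genes,
    compare_gene_lists,
    extend_contacts,
    select_contact_genes,
    viewpoint_proximity,
)
from rdna4c.io_formats import read_bedgraph, read_gene_annotation
from rdna4c.pipeline import load_genome

RESULTS = Path("results")


def main() -> None:
    paths = json.loads((RESULTS / "paths.json").read_text())
    chrom_sizes, bait = load_genome(paths["genome"])
    genes = read_gene_annotation(paths["genes"])
    manifest = TruthManifest.from_json(paths["truth"])
    cfg = PipelineConfig()
    lists = {}
    for cond in ("control", "heat_shock"):
        called = read_bedgraph(str(RESULTS / f"contacts_{cond}.bedGraph"))
        extended = extend_contacts(called, cfg.extension_bp, chrom_sizes)
        counts = assign_contacts_to_genes(extended, genes, condition=cond)
        lists[cond] = select_contact_genes(counts, cfg.gene_read_threshold)
        expected = manifest.expected_contact_genes(cond, cfg.gene_read_threshold)
        recall = len(expected & set(lists[cond])) / len(expected)
        print(
            f"{cond}: {len(lists[cond])} contact genes "
            f"(recall of planted genes: {recall:.2f})"
        )
        pd.Series(lists[cond], name="gene_id").to_csv(
            RESULTS / f"contact_genes_{cond}.tsv", sep="\t", index=False
        )
    venn = compare_gene_lists(lists)
    venn.to_frame().to_csv(RESULTS / "venn.tsv", sep="\t", index=False)
    both = len(venn.region(True, True))
    print(
        f"venn: {both} genes keep contacts under heat shock, "
        f"{len(venn.region(True, False))} lose them, "
        f"{len(venn.region(False, True))} gain them"
    )
    union = sorted(set(lists["control"]) | set(lists["heat_shock"]))
    table = viewpoint_proximity(bait, genes, union)
    table.to_csv(RESULTS / "viewpoint_proximity.tsv", sep="\t", index=False)
    cis = table[table["linked"]]
    if len(cis):
        print(
            f"nearest contact gene on the bait chromosome is "
            f"{int(cis.iloc[0]['distance_bp']):,} bp from the viewpoint"
        )


if __name__ == "__main__":
    main()
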