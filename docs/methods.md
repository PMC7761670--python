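# Methods

`rdna4c` implements a whole-genome 4C contact analysis for a single fixed
viewpoint — the ribosomal DNA cluster near the end of the *Drosophila* X
chromosome — together with the resampling machinery needed to decide which
of its findings could have arisen by chance. This note records the models,
the defaults and why they are what they are, what the synthetic data do and
do not emulate, and the numerical choices made where the design was open.

## Coordinate model

All coordinates inside the package are 0-based half-open; conversion
to/from 1-based conventions (GTF/GFF3 closed intervals, wiggle positions)
happens only in `io_formats`. Chromosome names are matched by exact string
equality; no silent "chr" aliasing is performed, because aliasing hides
data errors — a rename map at load time is the supported escape hatch.
`ContactTrack` (sorted, per-chromosome non-overlapping bedGraph records) is
the pipeline's central currency; readers validate the invariants and refuse
overlapping or negative records rather than repairing them.

## Contact calling

A contact site is called from two biological replicates per condition:

1. **Replicate intersection.** Records overlapping by at least one
   nucleotide are treated as the same contact; the output record covers
   exactly the intersection and carries the arithmetic mean of the two
   replicate values. When one record overlaps k partners, each pair yields
   its own intersection record; abutting outputs are merged only when their
   values are equal. The intersection (rather than the union) is the
   conservative choice and keeps the output a valid track.
2. **Repeat filtering.** A record is removed iff a single repeat entry
   fully contains it (`bedtools intersect -v -f 1.0` semantics). Partial
   overlaps survive unmodified. Containment against the *union* of repeats
   is deliberately not used: a record bridging two adjacent repeats is
   evidence of unique flanking sequence.
3. **Thresholding.** Mean reads ≥ 100, inclusive ("100 or more"). The
   threshold is justified by the overlap null below: chance overlap between
   independent gene lists is ~3–4%, so lists reproducible at ~90% across
   replicates cannot be threshold artefacts.
4. **Extension.** Contacts from a six-cutter digest are positionally
   uncertain by about ±2.5 kb, so each called site is extended by 2,500 bp
   on both sides (clamped at chromosome ends) before gene assignment.
   Extended intervals may overlap; they are no longer a track.

Gene assignment is multi-overlap: an extended contact contributes its full
read value to **every** gene body it overlaps by ≥ 1 bp (featureCounts
`-M -t gene` semantics); a 5 kb window bridging two genes is genuine
evidence for both. Genes with ≥ 100 assigned reads form the contact list,
sorted by descending reads, ties broken lexicographically for determinism.

## Replicate QC

Coverage is binned (50 bp default), each read apportioned to bins by
overlap fraction, and RPKM-normalized. The viewpoint chromosome X is
excluded from the library-size denominator — bait-proximal mapping would
otherwise dominate it — but still receives bins, and a flag controls
whether its bins enter the correlation. Outlier bins beyond
median + 200·MAD (per sample) are dropped when requested; the rule is
explicit because the upstream tool's exact rule is version-dependent.
Correlation is computed on untransformed values: log1p in the reference
tooling affects only scatterplot rendering.

## Differential model

Contact counts (rounded half-up, since replicate averaging produces
non-integers) and RNA-seq counts share one two-condition NB model:

* **Size factors**: median-of-ratios. factor_j = median over genes (with
  positive geometric mean) of count_gj / geomean_g.
* **Dispersion**: per-gene method of moments on normalized counts pooled
  within conditions, α = max(0, (s² − μ̄)/μ̄²), averaged across conditions
  with positive mean. With two replicates per condition this estimate is
  zero for roughly half the genes even under real overdispersion, which
  makes a naive Wald test anti-conservative (~16% of null genes at
  p < 0.05 in simulation). `run_differential` therefore floors every
  gene's dispersion at the cross-gene mean estimate — a one-step,
  transparent analogue of shrinkage-to-trend — bringing the null rate to
  ~4%. The local-regression dispersion fit and LFC shrinkage of the
  established NB tools are intentionally not replicated; an explicit,
  testable approximation was preferred, and `pydeseq2` serves as an
  independent cross-check in the test suite, not as the implementation.
* **Wald test**: log2fc = log2((μ̂₂+ε)/(μ̂₁+ε)) with ε = 0.5 so genes
  absent in one condition get large finite fold changes;
  se² = (1/ln2)² Σ_c (1/n_c)(1/max(μ̂_c, ε) + α) by the delta method;
  two-sided p from the standard normal; Benjamini–Hochberg over tested
  genes. All-zero genes are emitted flagged with p = padj = 1.
* A useful exact property: multiplying one sample's counts by c rescales
  all normalized counts uniformly by c^(1/n), so every log2fc is unchanged
  (up to the ε pseudo-count); the sample's size factor grows by
  c^((n−1)/n), not c, because gene-wise geometric means absorb the rest.

Expression testing is restricted to the contact-gene list *before* BH
adjustment, matching the study design of asking specifically whether
rDNA-contacting genes change transcription.

## Annotation

Feature classes are assigned from the site midpoint with priority
promoter > TTS > 5′UTR > 3′UTR > exon > intron > repeat_LTR >
repeat_other > intergenic. Windows are strand-aware: promoter
[TSS−1000, TSS+100), TTS [TES−100, TES+1000). The named upstream annotator
does not publish its parameters, so these are explicit configuration.
Exactly one class per site, by construction.

Chromatin-state assignment uses the fractional-overlap rule: a site belongs
to a state iff ≥ 50% (configurable) of its length lies in segments of that
state, accumulating across same-state segments. If several states qualify
(possible only at fractions ≤ 0.5) the larger overlap wins, ties to the
lower state label.

## Permutation nulls

**Gene-list overlap.** Each draw Fisher–Yates-shuffles the full universe of
unique gene names and takes the first k as a random list; the fraction of
it present in a fixed reference list is recorded. For k = 588 of
N = 17,748 the null is hypergeometric: mean 588/17,748 ≈ 0.0331, sd
≈ 0.0073 — the tests verify the Monte-Carlo estimate against this closed
form, and at 100,000 draws the sd estimate rounds to 0.007. Empirical
p-values use add-one smoothing, (1 + #{null ≥ observed})/(n + 1), so they
are never zero and remain valid under exchangeability.

**State enrichment.** Observed per-state site counts are compared with
counts recomputed under three segmentation shuffles:

* (a) `label_shuffle` — coordinates fixed, labels permuted genome-wide.
  Preserves all coordinates and the label multiset. Note it cannot
  preserve the (length, label) pairing, since labels move across segments
  of unequal length.
* (b) `segment_shuffle` — within each chromosome the (length, label)
  segments are reordered uniformly and coordinates rebuilt cumulatively
  from the chromosome start. Preserves the per-chromosome (length, label)
  multiset. (The prose description this scheme descends from is
  self-contradictory — "shuffle segments" yet "leaves the order intact" —
  and per-chromosome reordering is the reading implemented.)
* (c) `coord_and_state_shuffle` — all (length, label) segments pooled
  genome-wide, shuffled, and dealt back chromosome by chromosome until
  each chromosome's original total length is filled (the last chromosome
  takes the remainder). Preserves the genome-wide multiset; per-chromosome
  totals may drift by less than one segment length.

Per state the result carries enrichment and depletion empirical p-values
plus a pooled two-proportion z-test comparing the observed proportion
against all shuffles pooled. Every shuffle consumes an independent
substream spawned from the master seed, so results are reproducible and
order-independent.

## Metaprofiles

Signal is averaged in fixed bins across ±2,000 bp windows (50 bp bins,
midpoint anchor by default; the window is a choice — it resolves structure
finer than the ±2.5 kb contact resolution at negligible cost). Bins past a
chromosome end or without any signal record are missing (NaN), not zero;
zero-filling would bias edge bins downward.

## Synthetic data: what it emulates, and what it does not

The default preset is a desk-scale genome: four 1 Mb chromosome arms plus a
0.3 Mb bait chromosome whose last 50 kb plays the rDNA cluster, ~400
non-overlapping genes with strands/exons/UTRs, ~150 repeats, and a gapless
9-state tiling with segment lengths log-uniform on [1, 10] kb. All of the
study's thresholds (100 reads, ±2.5 kb, 50% overlap) remain meaningful at
this scale.

Planted structure, recorded in a truth manifest:

* 90 contact genes in five categories — retained (per-site NB mean 400 in
  both conditions), lost / gained (mean 400 in one condition, absent in the
  other), and up / down (150 ↔ 600, i.e. log2FC = ±2). Each gene gets 1–3
  sites of ~150 bp placed within assignment reach of the gene body and
  never wholly inside a repeat. The 400-read mean sits 4× above the
  100-read threshold so that calling failures reflect the caller, not
  boundary noise; the 150-read arm of modulated genes deliberately sits
  near the threshold, and recovery tests therefore score recall against
  genes whose planted per-condition total is ≥ 2× the gene threshold — a
  gene whose true signal is at or below threshold is not a miss.
* 15 decoy sites wholly inside repeat entries, at full contact strength;
  the containment filter must remove every one.
* A target fraction (0.7) of planted sites placed inside segments of state
  1, availability permitting; genes with state-1 segments in reach are
  preferred when drawing contact genes, and the *realized* per-state site
  distribution is written to the manifest (typically ~0.8 for state 1 once
  incidental hits are counted) so tests compare against what was actually
  planted.
* Sub-threshold background (300 sites, mean 10) scattered genome-wide, and
  expression counts with log2FC = ±2 planted in 30 contact genes.

Counts are NB(mean · λ, α) with variance = μ + αμ², where λ is a per-site
lognormal factor (σ = 0.5, unit mean) shared by all four samples at that
site. The shared factor produces replicate concordance; the NB term is
per-sample noise. The default α = 0.02 reflects well-behaved biological
replicates at these depths: the binned-coverage Pearson correlation between
replicates decomposes as Var(mλ) / (Var(mλ) + E[mλ] + α·E[(mλ)²]), and the
α term dominates, giving ~0.97 at α = 0.02.

What the generator does **not** emulate: sequence content (no reads, no
alignment, no mappability structure), ligation biochemistry and
restriction-fragment geometry, distance-decay of cis contact frequency,
copy-number or GC biases, and overlapping/nested gene models. Passing
recovery tests therefore demonstrates that the pipeline's logic is correct
under the statistical model the analysis itself assumes — not that the
model captures every artefact of real 4C libraries.

## Numerical and calibration choices

* Mean values from replicate intersection stay real through thresholding;
  rounding (half-up) happens only where counts enter the NB model.
* Empirical p-values use the add-one estimator throughout.
* Tie-breaks are deterministic everywhere (lexicographic gene ids, lower
  state label) so identical config + seed gives byte-identical outputs.
* Problem sizes in the analysis scripts and test suite are desk-scale by
  design: 2,000 shuffles per enrichment scheme in the analysis driver
  (10,000 is the configurable study default), 100,000 draws for the
  overlap null (the study value), and a null-calibration study of 100
  repeated enrichment runs at 20 sites × 499 shuffles. That calibration
  configuration was chosen because empirical p-values from permutation are
  discrete: with 9 states per run, the run-level event "no state reaches
  p ≤ 0.01" is only guaranteed at ~91% by exchangeability alone, while
  heavier tie structure (few sites, moderate shuffle count) keeps the
  per-run clean rate near 99%, which is what the run-level check assumes.
  The pooled fraction of p ≤ 0.01 across runs — the actual
  super-uniformity guarantee — is asserted as well.

## Known limitations

* The dispersion floor is global; with many truly low-dispersion genes it
  is conservative for them.
* The Wald normal approximation at n = 2 per condition is rough; the test
  suite pins its null behaviour to a tolerance band rather than claiming
  exactness.
* Scheme (c) shuffling can leave per-chromosome totals off by up to one
  segment length, and segments may extend past the original chromosome
  end; for enrichment counting this is immaterial, but the shuffled
  segmentation is not guaranteed to fit the genome exactly.
* `viewpoint_proximity` measures edge-to-edge gaps between the bait and
  gene bodies; other conventions (midpoint, TSS) would shift distances by
  up to a gene length.
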