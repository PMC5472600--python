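# Methods

This note documents the models and numerical conventions implemented in
`mullersig`, the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Promoter histone scoring

A gene's histone-modification level in one ChIP sample is derived from tag
(read 5′-end) positions in five steps:

1. **Window counting.** Tags are counted in windows of width *w* = 1050 bp
   placed every *s* = 50 bp from position 0 of each chromosome. A tag at
   position *p* is counted by every window containing it — exactly
   *w*/*s* = 21 windows for interior tags. Windows are genome-global (the
   grid does not depend on genes), so neighbouring genes share window
   values. The last windows of a chromosome may extend past its end; tags
   may not.
2. **Library normalization.** Each window count is divided by the library's
   total tag count, making tracks comparable between libraries of
   different depths (duplicating every tag *k*-fold leaves the normalized
   track bit-identical).
3. **Input subtraction.** The matched input (sonicated chromatin, no
   antibody) track is subtracted window-wise. Differences may be negative
   where the input locally exceeds the ChIP signal.
4. **log2 transform.** Values become log2(max(v, 0) + ε) with ε = 1e-9
   (configurable). Flooring at zero before the offset maps all depleted or
   neutral windows to a common floor log2(ε) while preserving the ordering
   of enriched windows. The transform is monotone, which is what the
   downstream rank-based normalization needs; the absolute value of the
   floor is immaterial after quantile normalization.
5. **TSS averaging.** The gene score is the mean of the values of all
   windows whose *centers* (start + *w*/2) lie within TSS ± 5 kb. The TSS
   is the transcript start for + genes and end − 1 for − genes (0-based
   half-open coordinates throughout). Genes on chromosomes without a track,
   or whose interval covers no window center, are excluded and reported.

Window values are anchored at window centers because the 50-bp slide makes
windows the natural "positions" of the track, and center anchoring treats
both strands symmetrically (mirroring the genome mirrors the scores).

The gene × sample matrix is then **quantile-normalized**: the reference
distribution is the row-wise mean of the column-sorted matrix, and the
rank-*i* value of every column is replaced by reference value *i*. Ties
within a column receive the mean of the reference values across the tied
rank span, which preserves within-column ordering (Spearman ρ = 1 against
the input) and makes the transform idempotent. With ties, column value
multisets can differ slightly after normalization because tie groups are
column-specific; for tie-free columns all multisets are identical.

## Expression gating

Small-RNA biotypes (miRNA, snoRNA, snRNA, rRNA, tRNA, scaRNA, misc_RNA)
are removed before analysis. A gene is specific to the positive fraction
(EPG) at a timepoint when (FPKM₊ + c)/(FPKM₋ + c) > 2, strictly, with
pseudocount c = 0.1 FPKM; the reciprocal rule defines ENG. The strict
inequality means a gene at exactly 2-fold belongs to neither set. The
pseudocount regularizes zero-FPKM denominators with minimal effect on
well-expressed genes; an optional minimum-FPKM floor (default off) can
additionally require the higher fraction to reach an absolute level.
Swapping the fractions swaps EPG and ENG exactly, and raising the fold
threshold can only shrink both sets.

## Clustering

**k-means** on log2(FPKM + 1) rows: Lloyd's algorithm with a seeded
k-means++-style initialization, Euclidean distance, convergence when
assignments stabilize (max 300 iterations). The implementation is local
(rather than scikit-learn's) because the contract requires a per-iteration
objective trace — the within-cluster sum of squares is asserted
non-increasing — and row-order-invariant seeded determinism; rows are
processed in lexicographic gene-id order, so permuting the input changes
nothing. Labels 0..k−1 are assigned in order of descending cluster mean so
that label identity is reproducible. scikit-learn's KMeans serves as an
independent cross-check in the test suite.

**Hierarchical clustering** of genes on the concatenated H3K4me3/H3K27me3
sample columns uses Ward linkage on Euclidean distances
(`scipy.cluster.hierarchy`), with the tree cut at a fixed k. Linkage and
distance are this package's documented choice — determinism and recorded
parameters are the achievable contract when the original choice is
unknown. Columns are not rescaled before clustering: both marks are on the
same quantile-normalized scale, so their natural variances carry signal.
Labels C1..Ck are ordered by descending cluster mean H3K27me3.

## Representative-gene selection

Per cluster: s(g) = Σ of the gene's H3K27me3 values over four samples (two
stages × two fractions, e.g. P2N, P2P, P5N, P5P); the top 18 genes by
descending s form the candidate pool (the whole cluster if smaller);
d(g) = (P2N − P2P)² + (P5N − P5P)²; the 3 representatives are the pool's
top genes by ascending d (`smallest_diff` mode, fraction-concordant genes)
or descending d (`largest_diff`, fraction-discordant genes). The two
squared differences are combined by summation by default (`max` is
available); the top-18 pool is per cluster, the only reading under which
every cluster yields three genes. All ties break lexicographically on
gene id, so the selection is fully deterministic.

## Statistics

Two-group contrasts use the classical pooled-variance Student t test
(two-sided; df = n₁ + n₂ − 2), with Welch's correction behind a flag. The
effect size is the point-biserial correlation — the absolute Pearson
correlation between the pooled values and a 0/1 group indicator — which
satisfies r = √(t²/(t² + df)). Bands: strong for r > 0.5, moderate for
0.3 < r ≤ 0.5, negligible otherwise; boundary values fall in the lower
band. Category enrichment is the per-cluster fraction of genes whose
annotation equals the queried label (exact match, no ontology expansion;
unannotated genes count as non-category). No multiple-testing correction
is applied.

## Synthetic data generator

The generator emulates a sorted-fraction retina study: 2,000 genes on two
16-Mb chromosomes (plus a small uncovered contig, below), expression for
six samples (embryonic whole-tissue E15 and E18; EGFP± fractions at P1 and
P4) and ChIP/input tag libraries for two antibodies × two Cd73 fractions ×
three stages (P2, P5, P8).

Planted structure and defaults:

* **Müller set** (150 genes): baseline expression in E15, E18 and the
  EGFP+ fractions, divided by 4 (`muller_fold`) in the EGFP− fractions —
  progenitor-shared genes that are *downregulated* in other lineages
  rather than glia-upregulated.
* **Rod set** (150 genes): baseline only in P4 EGFP−, 4-fold lower
  everywhere else — genes rising in the maturing rod-containing fraction.
* **TF-like subset** (60 of the Müller genes): labelled "transcription
  regulator" in the category table (on top of a 5% background TF rate) and
  carrying an 8-fold H3K27me3 tag-rate enrichment in TSS ± 2 kb in the
  Cd73⁺ libraries at all stages. All Müller genes carry the analogous
  H3K4me3 enrichment in the Cd73⁻ libraries. The ±2-kb enrichment sits
  inside the scored ±5-kb promoter window by construction.
* Baseline FPKM is lognormal with median 10 (spread 1.5 in log2 units);
  every expression cell gets multiplicative noise 2^N(0, σ) with σ = 0.25
  in log2 units, the package's working scale. Under these defaults the
  2-fold gate recovers the Müller set with sensitivity and precision above
  0.9 — the operating point the pipeline's contracts are stated at.
* ChIP tags: the background rate and the enrichment fold are *relative*
  intensities; all rates are scaled so each library's expected total is
  `library_size` = 2×10⁵ (Poisson). One input library per fraction × stage
  is shared by the two antibodies, since input chromatin is
  antibody-independent.
* TSSs are spaced ≥ 15 kb apart so a planted ±2-kb signal never bleeds
  into a neighbour's ±5-kb scoring window. The two 16-Mb chromosomes are
  sized to hold 2,000 genes at that spacing.
* 3% of genes (`frac_unscored`) are placed on a contig the ChIP libraries
  do not cover, emulating genes whose histone values are undetectable in
  real ChIP data and exercising the coverage-restriction stage.
* All randomness flows from one integer seed through per-stage
  `numpy` generators; identical seeds give bit-identical datasets.

What the generator does **not** emulate: overlapping or nested genes,
non-uniform mappability and GC bias, fragment-length effects, replicate
structure, broad-domain (non-promoter) H3K27me3 spreading, and
cross-sample FPKM normalization artifacts. Passing tests therefore show
the pipeline's operations are correct and recover structure of this
planted form — not that the biological conclusions of any particular real
dataset would be reproduced.

## Problem sizes

Unit and property tests run on scaled-down instances (tens of genes,
hundreds of tags, ≤ 60-kb chromosomes) where brute-force oracles —
direct per-gene window enumeration, greedy minimal-Ward merging,
sort-twice representative selection, textbook pooled-t — are exact and
fast. End-to-end checks use the full default simulation (2,000 genes,
2×10⁵-tag libraries) across 10 seeds. The acceptance script runs the
complete default-scale workflow in a few seconds.

## Known limitations

* The window grid is genome-global; a TSS-anchored grid would give each
  gene windows at fixed offsets but would not tile the genome. Both are
  defensible; the global grid is implemented and documented.
* The ε-floor before log2 compresses all depleted windows to one value;
  analyses that need signed depletion magnitudes should use the raw
  (pre-log2) tracks.
* Hierarchical cluster identities depend on linkage/distance choices;
  only the documented Ward/Euclidean configuration is supported.
* FPKM values are taken as given; no between-sample expression
  normalization is applied before gating.
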