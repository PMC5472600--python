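# mullersig

Promoter histone-modification scoring and gene-set analysis for sorted
cell fractions from the developing retina.

## The problem

Müller glia are the retina's intrinsic glial cells, born from the same
progenitor pool as retinal neurons. Because rod photoreceptors dominate the
tissue (>70% of cells), bulk measurements of the whole retina mostly
describe rods; finding Müller-glia-specific genes requires sorted cell
fractions. `mullersig` implements the computational chain for such a study:

1. **Expression gating.** Given FPKM tables of EGFP+ (glia-enriched) and
   EGFP− fractions at two timepoints, a gene is fraction-specific when its
   expression exceeds the opposite fraction by strictly more than 2-fold
   (with a pseudocount `c`): gene ∈ EPG iff (FPKM₊ + c)/(FPKM₋ + c) > 2.
   Small RNAs (miRNA, snoRNA, ...) are excluded first. Set algebra over the
   two timepoints yields shared and timepoint-specific gene sets.
2. **Promoter histone scoring.** For each ChIP sample (H3K4me3 or H3K27me3)
   with a matched input library, tags are counted in 1050-bp windows slid
   every 50 bp; window counts are divided by the library's total tag count;
   the input track is subtracted window-wise; the difference is log2-
   transformed (non-positive values floored at ε = 1e-9); and each gene's
   score is the mean over windows whose centers lie within TSS ± 5 kb. The
   gene × sample matrix is then quantile-normalized.
3. **Clustering.** Genes are clustered on their histone values
   (agglomerative, Ward linkage, Euclidean distance, labels C1..Ck ordered
   by descending mean H3K27me3), or on log2(FPKM+1) by seeded k-means.
4. **Enrichment and statistics.** Per-cluster fraction of genes annotated
   to a category (e.g. "transcription regulator"); two-group contrasts use
   the pooled-variance Student t test with the point-biserial correlation r
   as effect size, banded strong (r > 0.5) / moderate (0.3 < r ≤ 0.5) /
   negligible (r ≤ 0.3). Note r = √(t²/(t² + df)).
5. **Representative genes.** Per cluster, sum each gene's H3K27me3 level
   over four sorted samples, keep the top 18, score the squared
   between-fraction differences per stage, and return the top 3 by smallest
   or largest difference depending on the cluster's mode.

A synthetic-data generator (`mullersig.synthetic`) emulates the full study
design — annotation, expression tables, ChIP/input tag libraries — with
planted ground truth, so every stage is testable without any download.

## Worked example

```python
from mullersig import SimulationConfig, PipelineParams, run_synthetic

report, dataset = run_synthetic(SimulationConfig(seed=1),
                                PipelineParams(k_hier=2))
print(report["gate_sizes"])
print({lab: round(c["r"], 3) for lab, c in report["fraction_contrasts"].items()})
```

prints

```
{'epg_P1': 149, 'epg_P4': 154, 'eng_P1': 4, 'eng_P4': 151,
 'intersection': 148, 'union': 155, 'p4_only': 6}
{'C1': 0.941, 'C2': 0.04}
```

149 and 154 genes pass the 2-fold gate at P1 and P4 (the generator plants
150 progenitor-shared genes), 148 are shared between timepoints, and after
cutting the histone dendrogram at k=2 the C1 cluster — the planted
H3K27me3-high transcription-factor-like subset — shows a strong
Cd73⁺-vs-Cd73⁻ repressive-mark contrast (r = 0.94) while C2 does not.

The same workflow is available from the shell:

```
muller-sig run --seed 1 --outdir results/run1
muller-sig simulate --seed 1 --outdir data/        # files only
muller-sig gate --expr data/expr.tsv --pos P4_P --neg P4_N --out gate_P4.json
```

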