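"""End-to-end workflow: gating -> histone scoring -> clustering -> enrichment.

Stages run in the order of the underlying study design: small-RNA filtering,
fold-change gating at the two timepoints, gene-set algebra, promoter histone
scoring with quantile normalization, restriction to histone-covered genes,
hierarchical clustering, per-cluster summaries, category enrichment,
representative-gene selection and fraction-contrast statistics. Every stage
writes its artifact to the output directory (when given) along with a
manifest of all tunable parameters.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import io_formats as io
from .clustering import cluster_summary, hierarchical_histone
from .expression_gating import (fold_change_gate, filter_small_rnas,
                                restrict_to_measured, set_algebra)
from .histone_signal import (DEFAULT_EPSILON, DEFAULT_FLANK, DEFAULT_STEP,
                             DEFAULT_WIDTH, compute_histone_matrix)
from .representatives import LARGEST, SMALLEST, RepresentativeConfig, select_representatives
from .stats import category_fraction, compare_groups
from .synthetic import SimulationConfig, SyntheticDataset, generate_dataset


@dataclass
class PipelineParams:
    fold: float = 2.0
    pseudocount: float = 0.1
    min_fpkm: float = 0.0
    width: int = DEFAULT_WIDTH
    step: int = DEFAULT_STEP
    flank: int = DEFAULT_FLANK
    epsilon: float = DEFAULT_EPSILON
    k_hier: int = 7
    gene_set: str = "intersection"   # intersection | p4_only | union
    linkage: str = "ward"
    tf_label: str = "transcription regulator"
    rep_sum_samples: list = field(default_factory=lambda: [
        "H3K27me3.Cd73_N.P2", "H3K27me3.Cd73_P.P2",
        "H3K27me3.Cd73_N.P5", "H3K27me3.Cd73_P.P5"])
    rep_modes: dict = field(default_factory=dict)  # default derived from k_hier

    def modes_for(self, k: int) -> dict[str, str]:
        """Default per-cluster mode: high-H3K27me3 thirds get largest_diff."""
        if self.rep_modes:
            return dict(self.rep_modes)
        # mirrors the study's split for k=7 (C3, C6, C7 largest, rest smallest)
        if k == 7:
            return {f"C{i}": (LARGEST if i in (3, 6, 7) else SMALLEST)
                    for i in range(1, 8)}
        return {f"C{i}": SMALLEST for i in range(1, k + 1)}


def run_pipeline(dataset: SyntheticDataset, params: PipelineParams | None = None,
                 outdir: str | Path | None = None) -> dict:
    """Run every stage on a dataset; returns the structured report."""
    params = params or PipelineParams()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    kept_genes, filter_counts = filter_small_rnas(dataset.genes)
    kept_ids = {g.gene_id for g in kept_genes}
    expr = dataset.expression.loc[sorted(kept_ids & set(dataset.expression.index))]

    gate_p1 = fold_change_gate(expr, "P1_P", "P1_N", fold=params.fold,
                               pseudocount=params.pseudocount,
                               min_fpkm=params.min_fpkm, timepoint="P1")
    gate_p4 = fold_change_gate(expr, "P4_P", "P4_N", fold=params.fold,
                               pseudocount=params.pseudocount,
                               min_fpkm=params.min_fpkm, timepoint="P4")
    venn = set_algebra(gate_p1.epg, gate_p4.epg)

    matrix, raw_matrix = compute_histone_matrix(
        dataset.chip_pairs, kept_genes, dataset.chrom_lengths,
        width=params.width, step=params.step, flank=params.flank,
        epsilon=params.epsilon)

    target_set = {"intersection": venn["intersection"],
                  "p4_only": venn["b_only"],
                  "union": venn["union"]}[params.gene_set]
    measured, dropped = restrict_to_measured(target_set, matrix)

    partition = hierarchical_histone(matrix, measured, params.k_hier,
                                     linkage_method=params.linkage)
    summary = cluster_summary(partition, matrix.values.loc[sorted(measured)])
    enrichment = category_fraction(partition, dataset.categories, params.tf_label)

    reps = select_representatives(matrix, partition,
                                  RepresentativeConfig(
                                      sum_samples=list(params.rep_sum_samples),
                                      mode_per_cluster=params.modes_for(params.k_hier)))

    # per cluster: repressive mark contrast between the two ChIP fractions
    k27_p = matrix.select_samples(antibody="H3K27me3", fraction="Cd73_P")
    k27_n = matrix.select_samples(antibody="H3K27me3", fraction="Cd73_N")
    contrasts = {}
    for label in partition.labels:
        members = partition.members(label)
        block = matrix.values.loc[members]
        if len(members) >= 2:
            contrasts[str(label)] = compare_groups(
                block[k27_p].mean(axis=1).to_numpy(),
                block[k27_n].mean(axis=1).to_numpy())

    report = {
        "filter_counts": filter_counts,
        "gate_sizes": {"epg_P1": len(gate_p1.epg), "epg_P4": len(gate_p4.epg),
                       "eng_P1": len(gate_p1.eng), "eng_P4": len(gate_p4.eng),
                       "intersection": venn["sizes"]["intersection"],
                       "union": venn["sizes"]["union"],
                       "p4_only": venn["sizes"]["b_only"]},
        "histone_missing_genes": len(matrix.missing_genes),
        "measured": {"retained": len(measured), "dropped": len(dropped)},
        "clusters": {str(lab): len(partition.members(lab)) for lab in partition.labels},
        "enrichment": [{"cluster": e.cluster, "n_genes": e.n_genes,
                        "n_category": e.n_category, "fraction": e.fraction}
                       for e in enrichment],
        "representatives": reps,
        "fraction_contrasts": contrasts,
        "sets": {"epg_P1": sorted(gate_p1.epg), "epg_P4": sorted(gate_p4.epg),
                 "measured": sorted(measured)},
        "partition": {str(g): str(lab) for g, lab in sorted(partition.assignment.items())},
    }
    if out is not None:
        manifest = {"params": asdict(params), "simulation": asdict(dataset.config)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        io.write_matrix_tsv(matrix.values, out / "histone_normalized.tsv")
        io.write_matrix_tsv(raw_matrix.values, out / "histone_raw.tsv")
        summary.to_csv(out / "cluster_summary.tsv", sep="\t", index=False)
        (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def run_synthetic(config: SimulationConfig | None = None,
                  params: PipelineParams | None = None,
                  outdir=None) -> tuple[dict, SyntheticDataset]:
    """Generate a synthetic dataset and run the full pipeline on it."""
    dataset = generate_dataset(config or SimulationConfig())
    return run_pipeline(dataset, params, outdir), dataset
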