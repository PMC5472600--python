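"""Synthetic retina-like dataset with planted structure.

The generator emulates the study design the pipeline targets: bulk RNA
expression of sorted EGFP+/EGFP- retinal fractions at two postnatal
timepoints plus two embryonic whole-retina references, and H3K4me3/H3K27me3
ChIP tag libraries (with matched inputs) of Cd73+ rod and Cd73- non-rod
fractions at three stages. Planted ground truth:

* a "Müller" gene set expressed at baseline in progenitors (E15, E18) and in
  the EGFP+ fractions, down ``muller_fold`` in the EGFP- fractions;
* a "rod" set at baseline only in the P4 EGFP- fraction;
* a transcription-factor-like subset of the Müller set carrying elevated
  H3K27me3 around the TSS specifically in the Cd73+ libraries;
* Müller genes carry H3K4me3 enrichment in the Cd73- libraries.

Multiplicative expression noise is 2**N(0, sigma) per cell (sigma in log2
units, matching the pipeline's log2 conventions). ChIP background and
enrichment rates are relative intensities, scaled so each library's expected
total equals ``library_size``. A fraction of genes is placed on a contig the
ChIP libraries do not cover, emulating genes undetected in ChIP-seq.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .models import GeneModel, TagLibrary

EXPR_SAMPLES = ("E15", "E18", "P1_N", "P1_P", "P4_N", "P4_P")
TF_LABEL = "transcription regulator"
UNSCORED_CONTIG = "chrU"
_SMALL_RNA_CHOICES = ("miRNA", "snoRNA", "snRNA")


@dataclass
class SimulationConfig:
    seed: int = 20170615
    n_genes: int = 2000
    n_chroms: int = 2
    chrom_length: int = 16_000_000
    frac_small_rna: float = 0.05
    frac_unscored: float = 0.03
    n_muller: int = 150
    n_rod: int = 150
    n_tf_k27: int = 60
    expr_noise_sigma: float = 0.25      # log2 units
    muller_fold: float = 4.0
    chip_background_rate: float = 0.5   # tags/kb, relative intensity
    chip_enrichment_fold: float = 8.0
    library_size: int = 200_000
    tss_spacing: int = 15_000
    enrich_flank: int = 2_000
    tf_background_frac: float = 0.05
    stages: tuple = ("P2", "P5", "P8")
    fractions: tuple = ("Cd73_P", "Cd73_N")

    def __post_init__(self) -> None:
        if self.n_muller + self.n_rod > self.n_genes:
            raise ValueError("n_muller + n_rod exceeds n_genes")
        if self.n_tf_k27 > self.n_muller:
            raise ValueError("n_tf_k27 must be a subset of the Müller set")
        if self.muller_fold <= 1 or self.chip_enrichment_fold <= 1:
            raise ValueError("fold parameters must exceed 1")

    @property
    def scored_chroms(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        """Lengths of the ChIP-covered chromosomes (excludes the unscored contig)."""
        return {c: self.chrom_length for c in self.scored_chroms}


@dataclass
class GroundTruth:
    muller_genes: list[str]
    rod_genes: list[str]
    tf_k27_genes: list[str]
    unscored_genes: list[str]
    true_fold: dict[str, float]
    k27_enriched_fraction: str = "Cd73_P"
    k4_enriched_fraction: str = "Cd73_N"


def write_truth(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(truth), fh, indent=1, sort_keys=True)


def read_truth(path) -> GroundTruth:
    with open(path) as fh:
        return GroundTruth(**json.load(fh))


def generate_annotation(config: SimulationConfig,
                        ) -> tuple[list[GeneModel], dict[str, str], GroundTruth]:
    """Place genes, assign biotypes/categories and choose the planted sets."""
    rng = np.random.default_rng([config.seed, 1])
    n = config.n_genes
    n_unscored = round(config.frac_unscored * n)
    n_scored = n - n_unscored
    margin = 10_000
    alloc: list[tuple[str, int]] = []
    per = n_scored // config.n_chroms
    rem = n_scored - per * config.n_chroms
    for i, chrom in enumerate(config.scored_chroms):
        alloc.append((chrom, per + (1 if i < rem else 0)))
    if n_unscored:
        alloc.append((UNSCORED_CONTIG, n_unscored))

    tss_by_gene: list[tuple[str, int]] = []
    for chrom, n_c in alloc:
        if n_c == 0:
            continue
        spacing = (config.chrom_length - 2 * margin) // n_c
        if spacing < config.tss_spacing:
            raise ValueError(
                f"{chrom}: cannot place {n_c} genes with TSS spacing >= "
                f"{config.tss_spacing} in {config.chrom_length} bp")
        jitter = rng.integers(0, max(1, spacing - config.tss_spacing + 1), size=n_c)
        for i in range(n_c):
            tss_by_gene.append((chrom, int(margin + i * spacing + jitter[i])))

    n_small = round(config.frac_small_rna * n)
    small_idx = set(rng.choice(n, size=n_small, replace=False).tolist())
    # planted sets avoid small RNAs but may land on the uncovered contig,
    # emulating genes whose histone values are undetected in the ChIP data
    eligible = [i for i in range(n) if i not in small_idx]
    picked = rng.choice(len(eligible), size=config.n_muller + config.n_rod,
                        replace=False)
    muller_idx = {eligible[j] for j in picked[: config.n_muller]}
    rod_idx = {eligible[j] for j in picked[config.n_muller:]}
    muller_sorted = sorted(muller_idx)
    tf_pick = rng.choice(len(muller_sorted), size=config.n_tf_k27, replace=False)
    tf_idx = {muller_sorted[j] for j in tf_pick}

    genes: list[GeneModel] = []
    categories: dict[str, str] = {}
    strands = rng.choice(["+", "-"], size=n)
    lengths = rng.integers(2_000, 20_000, size=n)
    small_types = rng.choice(_SMALL_RNA_CHOICES, size=n)
    bg_tf = rng.random(n) < config.tf_background_frac
    for i, (chrom, tss) in enumerate(tss_by_gene):
        gene_id = f"G{i:05d}"
        strand = str(strands[i])
        length = int(lengths[i])
        if strand == "+":
            tx_start, tx_end = tss, min(tss + length, config.chrom_length)
        else:
            tx_start, tx_end = max(tss + 1 - length, 0), tss + 1
        biotype = str(small_types[i]) if i in small_idx else "protein_coding"
        category = TF_LABEL if (i in tf_idx or (bg_tf[i] and i not in small_idx)) else "other"
        genes.append(GeneModel(gene_id, chrom, strand, tx_start, tx_end,
                               biotype, category))
        categories[gene_id] = category

    gid = lambda idx: sorted(f"G{i:05d}" for i in idx)
    true_fold = {f"G{i:05d}": float(config.muller_fold) for i in sorted(muller_idx | rod_idx)}
    truth = GroundTruth(
        muller_genes=gid(muller_idx), rod_genes=gid(rod_idx),
        tf_k27_genes=gid(tf_idx),
        unscored_genes=sorted(g.gene_id for g in genes if g.chrom == UNSCORED_CONTIG),
        true_fold=true_fold)
    return genes, categories, truth


def generate_expression(config: SimulationConfig, truth: GroundTruth,
                        genes: list[GeneModel]) -> pd.DataFrame:
    """FPKM table for E15, E18 and the P1/P4 EGFP+/- fractions."""
    rng = np.random.default_rng([config.seed, 2])
    gene_ids = [g.gene_id for g in genes]
    n = len(gene_ids)
    base = 10.0 * np.power(2.0, rng.normal(0.0, 1.5, size=n))  # median ~10 FPKM
    means = pd.DataFrame(np.tile(base[:, None], (1, len(EXPR_SAMPLES))),
                         index=gene_ids, columns=EXPR_SAMPLES)
    muller = [g for g in truth.muller_genes if g in means.index]
    rod = [g for g in truth.rod_genes if g in means.index]
    means.loc[muller, ["P1_N", "P4_N"]] /= config.muller_fold
    means.loc[rod, ["E15", "E18", "P1_N", "P1_P", "P4_P"]] /= config.muller_fold
    if config.expr_noise_sigma > 0:
        noise = np.power(2.0, rng.normal(0.0, config.expr_noise_sigma, size=means.shape))
        means = means * noise
    means.index.name = "gene_id"
    return means


def _enriched_genes(config: SimulationConfig, truth: GroundTruth,
                    antibody: str, fraction: str) -> list[str]:
    if antibody == "H3K27me3" and fraction == truth.k27_enriched_fraction:
        return truth.tf_k27_genes
    if antibody == "H3K4me3" and fraction == truth.k4_enriched_fraction:
        return truth.muller_genes
    return []


def _draw_library(rng: np.random.Generator, config: SimulationConfig,
                  sample_id: str, antibody: str, fraction: str, stage: str,
                  windows: list[tuple[str, int, int]]) -> TagLibrary:
    """Draw one library: uniform background plus extra rate in ``windows``.

    Rates are relative (background 1 per bp, ``chip_enrichment_fold`` per bp
    inside an enriched window); the expected total is ``library_size``.
    """
    chroms = config.scored_chroms
    genome_len = config.n_chroms * config.chrom_length
    extra = np.array([(config.chip_enrichment_fold - 1.0) * (e - s)
                      for _, s, e in windows])
    total_mass = genome_len + extra.sum()
    n_tags = rng.poisson(config.library_size)
    probs = np.concatenate([[genome_len / total_mass], extra / total_mass])
    counts = rng.multinomial(n_tags, probs)
    positions: dict[str, list[np.ndarray]] = {c: [] for c in chroms}
    n_bg = counts[0]
    bg_chrom = rng.integers(0, config.n_chroms, size=n_bg)
    bg_pos = rng.integers(0, config.chrom_length, size=n_bg)
    for ci, chrom in enumerate(chroms):
        positions[chrom].append(bg_pos[bg_chrom == ci])
    for (chrom, s, e), c in zip(windows, counts[1:]):
        if c:
            positions[chrom].append(rng.integers(s, e, size=c))
    merged = {c: np.sort(np.concatenate(v)) if v else np.empty(0, dtype=np.int64)
              for c, v in positions.items()}
    return TagLibrary(sample_id, merged, antibody=antibody,
                      fraction=fraction, stage=stage)


def generate_chip(config: SimulationConfig, truth: GroundTruth,
                  genes: list[GeneModel],
                  ) -> list[tuple[TagLibrary, TagLibrary]]:
    """All (test, input) library pairs: 2 antibodies x fractions x stages.

    One input (background-only) library per fraction x stage is shared by the
    two antibodies of that sample.
    """
    rng = np.random.default_rng([config.seed, 3])
    tss_of = {g.gene_id: (g.chrom, g.tss) for g in genes}
    pairs = []
    for fraction in config.fractions:
        for stage in config.stages:
            ctrl = _draw_library(rng, config, f"input.{fraction}.{stage}",
                                 "input", fraction, stage, [])
            for antibody in ("H3K4me3", "H3K27me3"):
                enriched = _enriched_genes(config, truth, antibody, fraction)
                windows = []
                for g in enriched:
                    chrom, tss = tss_of[g]
                    if chrom not in config.chrom_lengths:  # uncovered contig
                        continue
                    windows.append((chrom, max(0, tss - config.enrich_flank),
                                    min(config.chrom_length, tss + config.enrich_flank + 1)))
                test = _draw_library(rng, config, f"{antibody}.{fraction}.{stage}",
                                     antibody, fraction, stage, windows)
                pairs.append((test, ctrl))
    return pairs


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genes: list[GeneModel]
    categories: dict[str, str]
    expression: pd.DataFrame
    chip_pairs: list[tuple[TagLibrary, TagLibrary]] = field(repr=False)
    truth: GroundTruth = None

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return self.config.chrom_lengths


def generate_dataset(config: SimulationConfig, with_chip: bool = True) -> SyntheticDataset:
    """Generate the full dataset (annotation, categories, expression, ChIP, truth)."""
    genes, categories, truth = generate_annotation(config)
    expr = generate_expression(config, truth, genes)
    chip = generate_chip(config, truth, genes) if with_chip else []
    return SyntheticDataset(config, genes, categories, expr, chip, truth)


def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """Write the dataset to disk in the formats the readers accept."""
    from . import io_formats as io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_gene_annotation(dataset.genes, outdir / "genes.bed")
    io.write_category_table(dataset.categories, outdir / "categories.tsv")
    io.write_matrix_tsv(dataset.expression, outdir / "expr.tsv")
    write_truth(dataset.truth, outdir / "truth.json")
    chip_dir = outdir / "chip"
    chip_dir.mkdir(exist_ok=True)
    written = set()
    for test, ctrl in dataset.chip_pairs:
        io.write_tag_bed(test, chip_dir / f"{test.sample_id}.bed")
        if ctrl.sample_id not in written:
            io.write_tag_bed(ctrl, chip_dir / f"{ctrl.sample_id}.bed")
            written.add(ctrl.sample_id)
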