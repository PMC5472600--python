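"""Small-RNA filtering, >2-fold expression gating and gene-set algebra.

A gene is fraction-specific ("EPG", EGFP-positive gene) at a timepoint when
its FPKM in the positive fraction exceeds the negative fraction by more than
a fold threshold (strictly), and vice versa for "ENG". A pseudocount guards
zero-FPKM denominators.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .models import SMALL_RNA_BIOTYPES, GeneModel, TssSignalMatrix


@dataclass
class GateResult:
    """Gene sets specific to the positive (epg) and negative (eng) fraction."""

    timepoint: str
    epg: set[str]
    eng: set[str]
    fold_threshold: float = 2.0
    pseudocount: float = 0.1

    def __post_init__(self) -> None:
        if self.epg & self.eng:
            raise ValueError("epg and eng overlap")


def filter_small_rnas(genes: list[GeneModel],
                      excluded_biotypes: frozenset[str] | set[str] = SMALL_RNA_BIOTYPES,
                      ) -> tuple[list[GeneModel], dict[str, int]]:
    """Drop small-RNA genes; returns (kept genes, before/after counts)."""
    kept = [g for g in genes if g.biotype not in excluded_biotypes]
    counts = {"before": len(genes), "after": len(kept),
              "excluded": len(genes) - len(kept)}
    if not kept:
        warnings.warn("all genes excluded by biotype filter")
    return kept, counts


def fold_change_gate(expr: pd.DataFrame, pos_sample: str, neg_sample: str,
                     fold: float = 2.0, pseudocount: float = 0.1,
                     min_fpkm: float = 0.0, timepoint: str = "",
                     ) -> GateResult:
    """Assign genes to epg/eng by a strict fold-ratio rule.

    gene in epg  iff  (FPKM_pos + c) / (FPKM_neg + c) > fold
    gene in eng  iff  (FPKM_neg + c) / (FPKM_pos + c) > fold

    ``min_fpkm`` optionally requires the higher fraction to reach a floor
    (0 disables it; the default).
    """
    if pos_sample == neg_sample:
        raise ValueError("pos_sample and neg_sample must differ")
    if fold <= 1:
        raise ValueError("fold threshold must exceed 1")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    pos = expr[pos_sample] + pseudocount
    neg = expr[neg_sample] + pseudocount
    epg_mask = (pos / neg > fold) & (expr[pos_sample] >= min_fpkm)
    eng_mask = (neg / pos > fold) & (expr[neg_sample] >= min_fpkm)
    return GateResult(timepoint or f"{pos_sample}_vs_{neg_sample}",
                      set(expr.index[epg_mask]), set(expr.index[eng_mask]),
                      fold_threshold=fold, pseudocount=pseudocount)


def set_algebra(a: set[str], b: set[str]) -> dict:
    """Intersection/union/exclusive sets with sizes; checks inclusion-exclusion."""
    a, b = set(a), set(b)
    result = {
        "intersection": a & b,
        "union": a | b,
        "a_only": a - b,
        "b_only": b - a,
    }
    sizes = {key: len(val) for key, val in result.items()}
    sizes["a"], sizes["b"] = len(a), len(b)
    assert sizes["union"] == sizes["a"] + sizes["b"] - sizes["intersection"]
    result["sizes"] = sizes
    return result


def restrict_to_measured(genes: set[str], matrix: TssSignalMatrix,
                         ) -> tuple[set[str], set[str]]:
    """Intersect a gene set with the genes covered by a histone matrix.

    Returns (retained, dropped).
    """
    covered = set(matrix.gene_ids)
    retained = set(genes) & covered
    return retained, set(genes) - retained
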