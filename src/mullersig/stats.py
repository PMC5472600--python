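"""Per-cluster category enrichment and two-group statistics.

Group comparisons report the classical two-sample t test together with a
point-biserial effect size r (the Pearson correlation between the pooled
values and a 0/1 group indicator), banded as strong (r > 0.5), moderate
(0.3 < r <= 0.5) or negligible (r <= 0.3).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .models import ClusterPartition

BAND_STRONG, BAND_MODERATE, BAND_NEGLIGIBLE = "strong", "moderate", "negligible"


@dataclass(frozen=True)
class EffectSizeBand:
    r: float
    band: str


@dataclass(frozen=True)
class ClusterEnrichment:
    cluster: str
    n_genes: int
    n_category: int

    @property
    def fraction(self) -> float:
        return self.n_category / self.n_genes


def band_of(r: float) -> str:
    """Effect-size band; boundary values fall in the lower band (strict >)."""
    if r > 0.5:
        return BAND_STRONG
    if r > 0.3:
        return BAND_MODERATE
    return BAND_NEGLIGIBLE


def category_fraction(partition: ClusterPartition, annotation: dict[str, str],
                      label: str = "transcription regulator",
                      ) -> list[ClusterEnrichment]:
    """Per-cluster fraction of genes annotated with ``label``.

    Genes absent from the annotation count as non-category.
    """
    if not partition.assignment:
        raise ValueError("empty partition")
    out = []
    for cluster in partition.labels:
        members = partition.members(cluster)
        n_cat = sum(1 for g in members if annotation.get(g) == label)
        out.append(ClusterEnrichment(str(cluster), len(members), n_cat))
    return out


def students_t(group_a, group_b, equal_var: bool = True) -> dict:
    """Two-sided two-sample t test (pooled-variance by default).

    Returns {'t', 'df', 'p'}; df = n_a + n_b - 2 for the pooled test,
    Welch-Satterthwaite otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    df = a.size + b.size - 2 if equal_var else float(res.df)
    return {"t": float(res.statistic), "df": float(df), "p": float(res.pvalue)}


def point_biserial_r(group_a, group_b) -> EffectSizeBand:
    """|Pearson r| between pooled values and the 0/1 group indicator."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size + b.size < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        raise ValueError("zero total variance: effect size undefined")
    indicator = np.concatenate([np.ones(a.size), np.zeros(b.size)])
    r = abs(float(np.corrcoef(pooled, indicator)[0, 1]))
    return EffectSizeBand(r, band_of(r))


def compare_groups(values_a, values_b, equal_var: bool = True) -> dict:
    """Bundle t test and effect size for one two-group comparison."""
    t = students_t(values_a, values_b, equal_var=equal_var)
    eff = point_biserial_r(values_a, values_b)
    return {**t, "r": eff.r, "band": eff.band}


def compare_clusters(matrix: pd.DataFrame, partition: ClusterPartition,
                     cluster_a, cluster_b, sample: str) -> dict:
    """Compare one sample's values between two clusters of a partition."""
    a = matrix.loc[[g for g in partition.members(cluster_a) if g in matrix.index], sample]
    b = matrix.loc[[g for g in partition.members(cluster_b) if g in matrix.index], sample]
    return compare_groups(a.to_numpy(), b.to_numpy())
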