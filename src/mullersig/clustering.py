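"""Clustering of gene matrices.

Expression clustering uses seeded k-means (Lloyd's algorithm with a
k-means++-style initialization) on log2(FPKM + 1) rows. Histone-value
clustering is agglomerative with Ward linkage and Euclidean distance.
Both are deterministic for a given seed and invariant to input row order
(rows are processed in lexicographic gene-id order).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .models import ClusterPartition, TssSignalMatrix

KMEANS_MAX_ITER = 300


@dataclass
class KMeansResult:
    partition: ClusterPartition
    centers: np.ndarray
    inertia_trace: list[float]  # objective after each assignment step


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total > 0:
            idx = rng.choice(n, p=d2 / total)
        else:
            idx = rng.integers(n)
        centers[j] = X[idx]
        d2 = np.minimum(d2, ((X - centers[j]) ** 2).sum(axis=1))
    return centers


def _lloyd(X: np.ndarray, k: int, seed: int,
           max_iter: int = KMEANS_MAX_ITER) -> tuple[np.ndarray, np.ndarray, list[float]]:
    rng = np.random.default_rng(seed)
    centers = _kmeanspp_init(X, k, rng)
    labels = None
    trace: list[float] = []
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        trace.append(float(d2[np.arange(X.shape[0]), new_labels].sum()))
        if labels is not None and np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            mask = labels == j
            if mask.any():
                centers[j] = X[mask].mean(axis=0)
            else:  # re-seed an emptied cluster at the worst-fit point
                centers[j] = X[d2.min(axis=1).argmax()]
    return labels, centers, trace


def kmeans_expression(expr: pd.DataFrame, k: int = 4, seed: int = 0,
                      transform=lambda v: np.log2(v + 1.0),
                      ) -> KMeansResult:
    """Seeded k-means of genes on transformed expression rows.

    Labels 0..k-1 are ordered by descending cluster mean of the transformed
    values (label 0 = highest overall mean), so label identity is reproducible.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    expr = expr.sort_index()  # row-order invariance
    X = transform(expr.to_numpy(dtype=float))
    if np.unique(X, axis=0).shape[0] < k:
        raise ValueError(f"fewer than k={k} distinct rows after transform")
    labels, centers, trace = _lloyd(X, k, seed)
    # relabel by descending cluster mean
    means = np.array([X[labels == j].mean() for j in range(k)])
    new_of_old = np.empty(k, dtype=int)
    new_of_old[np.argsort(-means, kind="stable")] = np.arange(k)
    labels = new_of_old[labels]
    centers = centers[np.argsort(new_of_old, kind="stable")]
    assignment = {g: int(lab) for g, lab in zip(expr.index, labels)}
    part = ClusterPartition("kmeans", k, assignment, seed=seed)
    return KMeansResult(part, centers, trace)


def hierarchical_histone(matrix: TssSignalMatrix, gene_set: set[str] | None,
                         k: int, linkage_method: str = "ward",
                         ) -> ClusterPartition:
    """Ward/Euclidean agglomerative clustering of genes on histone values.

    Columns are the concatenated H3K4me3 and H3K27me3 sample scores. The tree
    is cut at k clusters; labels C1..Ck are ordered by descending cluster mean
    H3K27me3 (all H3K27me3 columns, falling back to all columns if the matrix
    carries no antibody metadata).
    """
    values = matrix.values
    if gene_set is not None:
        genes = sorted(set(gene_set) & set(values.index))
    else:
        genes = sorted(values.index)
    if k > len(genes):
        raise ValueError(f"k={k} exceeds number of genes ({len(genes)})")
    sub = values.loc[genes]
    Z = linkage(sub.to_numpy(dtype=float), method=linkage_method)
    flat = fcluster(Z, t=k, criterion="maxclust")
    if len(set(flat)) != k:
        raise ValueError(f"tree cut produced {len(set(flat))} clusters, wanted {k}")
    k27_cols = matrix.select_samples(antibody="H3K27me3") or list(sub.columns)
    k27 = sub[k27_cols].to_numpy(dtype=float)
    raw_labels = sorted(set(flat))
    order = sorted(raw_labels, key=lambda lab: -k27[flat == lab].mean())
    rename = {old: f"C{i + 1}" for i, old in enumerate(order)}
    assignment = {g: rename[lab] for g, lab in zip(genes, flat)}
    return ClusterPartition("hierarchical", k, assignment, linkage=linkage_method)


def cluster_summary(partition: ClusterPartition, values: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster, per-sample five-number-ish summary (n, mean, q1, median, q3)."""
    rows = []
    for label in partition.labels:
        members = partition.members(label)
        missing = set(members) - set(values.index)
        if missing:
            raise ValueError(f"cluster {label}: values missing for {sorted(missing)[:3]}...")
        block = values.loc[members]
        if block.empty:
            raise ValueError(f"cluster {label} is empty")
        for sample in values.columns:
            col = block[sample]
            rows.append({
                "cluster": label, "sample": sample, "n": len(col),
                "mean": col.mean(), "q1": col.quantile(0.25),
                "median": col.median(), "q3": col.quantile(0.75),
            })
    return pd.DataFrame(rows)
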