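"""Selection of representative genes per cluster for ChIP-qPCR follow-up.

For each gene the total repressive-mark (H3K27me3) level over four sorted
samples (two stages x two fractions) is summed; the cluster's top genes by
that sum form a candidate pool, within which genes are ranked by the squared
between-fraction differences at each stage — taking the 3 most fraction-
concordant genes (smallest difference) or most fraction-discordant genes
(largest difference), depending on the cluster's mode.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .models import ClusterPartition, TssSignalMatrix

SMALLEST, LARGEST = "smallest_diff", "largest_diff"


@dataclass
class RepresentativeConfig:
    """Samples and constants of the selection.

    ``sum_samples`` order is [stage1_neg, stage1_pos, stage2_neg, stage2_pos];
    consecutive pairs are differenced. ``combine`` joins the two squared
    differences by 'sum' (default) or 'max'.
    """

    sum_samples: list[str]
    mode_per_cluster: dict[str, str] = field(default_factory=dict)
    top_n_sum: int = 18
    top_n_select: int = 3
    combine: str = "sum"

    def __post_init__(self) -> None:
        if self.top_n_select > self.top_n_sum:
            raise ValueError("top_n_select must be <= top_n_sum")
        if len(self.sum_samples) % 2:
            raise ValueError("sum_samples must pair up")
        if self.combine not in ("sum", "max"):
            raise ValueError("combine must be 'sum' or 'max'")
        for mode in self.mode_per_cluster.values():
            if mode not in (SMALLEST, LARGEST):
                raise ValueError(f"unknown mode {mode!r}")


def select_representatives(matrix: TssSignalMatrix | pd.DataFrame,
                           partition: ClusterPartition,
                           config: RepresentativeConfig,
                           ) -> dict[str, list[str]]:
    """Pick ``top_n_select`` representative genes per cluster.

    Per cluster: (1) s(g) = sum of the gene's values over ``sum_samples``;
    (2) keep the top ``top_n_sum`` genes by descending s (all, if fewer);
    (3) d(g) combines the squared difference of each consecutive sample pair;
    (4) return the top ``top_n_select`` by ascending d (smallest_diff mode)
    or descending d (largest_diff mode). Ties break lexicographically.
    """
    values = matrix.values if isinstance(matrix, TssSignalMatrix) else matrix
    missing_cols = [c for c in config.sum_samples if c not in values.columns]
    if missing_cols:
        raise ValueError(f"matrix lacks sample columns {missing_cols}")
    out: dict[str, list[str]] = {}
    for label in partition.labels:
        members = [g for g in partition.members(label) if g in values.index]
        if not members:
            raise ValueError(f"cluster {label} has no genes in the matrix")
        mode = config.mode_per_cluster.get(str(label), SMALLEST)
        block = values.loc[members, config.sum_samples]
        s = block.sum(axis=1)
        pool = sorted(members, key=lambda g: (-s[g], g))[: config.top_n_sum]
        diffs = []
        for i in range(0, len(config.sum_samples), 2):
            a, b = config.sum_samples[i], config.sum_samples[i + 1]
            diffs.append((block[a] - block[b]) ** 2)
        d = sum(diffs) if config.combine == "sum" else pd.concat(diffs, axis=1).max(axis=1)
        sign = 1.0 if mode == SMALLEST else -1.0
        chosen = sorted(pool, key=lambda g: (sign * d[g], g))[: config.top_n_select]
        out[str(label)] = chosen
    return out
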