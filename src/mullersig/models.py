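"""Core domain types shared across the pipeline.

Coordinates are 0-based half-open everywhere inside the package;
conversions from 1-based formats happen only at I/O boundaries.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: biotypes dropped before any promoter-level analysis
SMALL_RNA_BIOTYPES = frozenset(
    {"miRNA", "snoRNA", "snRNA", "rRNA", "tRNA", "scaRNA", "misc_RNA"}
)


@dataclass(frozen=True)
class GeneModel:
    """One gene: location, strand, biotype and optional category label."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int  # 0-based inclusive
    tx_end: int    # 0-based exclusive
    biotype: str = "protein_coding"
    category: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r} for {self.gene_id}")
        if not self.tx_start < self.tx_end:
            raise ValueError(
                f"{self.gene_id}: tx_start ({self.tx_start}) must be < tx_end ({self.tx_end})"
            )
        if self.tx_start < 0:
            raise ValueError(f"{self.gene_id}: negative tx_start")

    @property
    def tss(self) -> int:
        """Transcription start site (0-based position of the first base)."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1


@dataclass
class TagLibrary:
    """One sample's aligned ChIP (or input) tags, reduced to 5' positions."""

    sample_id: str
    positions: dict[str, np.ndarray]  # chrom -> sorted int64 positions
    antibody: str = "input"           # H3K4me3 | H3K27me3 | input
    fraction: str = ""                # e.g. Cd73_P, Cd73_N
    stage: str = ""                   # e.g. P2

    def __post_init__(self) -> None:
        clean = {}
        for chrom, pos in self.positions.items():
            arr = np.asarray(pos, dtype=np.int64)
            if arr.size and arr.min() < 0:
                raise ValueError(f"{self.sample_id}: negative tag position on {chrom}")
            clean[chrom] = np.sort(arr)
        self.positions = clean

    @property
    def total_tags(self) -> int:
        return int(sum(arr.size for arr in self.positions.values()))

    @property
    def chroms(self) -> list[str]:
        return sorted(self.positions)


@dataclass
class WindowTrack:
    """Sliding-window values along one chromosome.

    Window i spans [start0 + i*step, start0 + i*step + width); its value is
    anchored at the window center start + width/2.
    """

    chrom: str
    values: np.ndarray
    width: int = 1050
    step: int = 50
    start0: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite window value on {self.chrom}")

    @property
    def starts(self) -> np.ndarray:
        return self.start0 + np.arange(self.values.size, dtype=np.int64) * self.step

    @property
    def centers(self) -> np.ndarray:
        return self.starts + self.width / 2

    def same_grid(self, other: "WindowTrack") -> bool:
        return (
            self.chrom == other.chrom
            and self.width == other.width
            and self.step == other.step
            and self.start0 == other.start0
            and self.values.size == other.values.size
        )


@dataclass
class TssSignalMatrix:
    """Gene x sample matrix of TSS-averaged histone values.

    ``values`` rows are gene ids, columns sample ids. ``samples`` carries
    per-column metadata (antibody, fraction, stage). ``missing_genes`` lists
    genes that overlapped no window center and were excluded.
    """

    values: pd.DataFrame
    samples: pd.DataFrame  # index = sample_id; columns antibody, fraction, stage
    normalized: bool = False
    flank: int = 5000
    missing_genes: list[str] = field(default_factory=list)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def select_samples(self, antibody: str | None = None,
                       fraction: str | None = None,
                       stage: str | None = None) -> list[str]:
        """Sample ids matching the given metadata filters."""
        mask = pd.Series(True, index=self.samples.index)
        if antibody is not None:
            mask &= self.samples["antibody"] == antibody
        if fraction is not None:
            mask &= self.samples["fraction"] == fraction
        if stage is not None:
            mask &= self.samples["stage"] == stage
        return list(self.samples.index[mask])


@dataclass
class ClusterPartition:
    """Gene -> cluster-label assignment with provenance."""

    method: str                    # kmeans | hierarchical
    k: int
    assignment: dict[str, object]  # gene_id -> label (int for kmeans, 'C1'.. for hier)
    seed: Optional[int] = None
    linkage: Optional[str] = None

    def __post_init__(self) -> None:
        labels = set(self.assignment.values())
        if len(labels) != self.k:
            raise ValueError(
                f"partition has {len(labels)} non-empty clusters, expected k={self.k}"
            )

    def members(self, label) -> list[str]:
        return sorted(g for g, lab in self.assignment.items() if lab == label)

    @property
    def labels(self) -> list:
        return sorted(set(self.assignment.values()), key=str)
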