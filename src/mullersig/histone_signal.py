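"""Promoter histone-modification scoring from ChIP tag libraries.

The score of a gene in one ChIP sample is computed in five steps:

1. count tags in 1050-bp windows slid every 50 bp along each chromosome;
2. divide every window count by the library's total tag count;
3. subtract the matched input (control) sample's track, window-wise;
4. convert to log2, flooring non-positive differences at a small epsilon;
5. average the window values whose centers fall within TSS +/- 5 kb.

The resulting gene x sample matrix is then quantile-normalized across
samples so every column shares one value distribution.
"""
from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .models import GeneModel, TagLibrary, TssSignalMatrix, WindowTrack

DEFAULT_WIDTH = 1050
DEFAULT_STEP = 50
DEFAULT_FLANK = 5000
DEFAULT_EPSILON = 1e-9


def count_window_tags(library: TagLibrary, chrom_lengths: dict[str, int],
                      width: int = DEFAULT_WIDTH, step: int = DEFAULT_STEP,
                      ) -> dict[str, WindowTrack]:
    """Count tags per sliding window on every chromosome.

    Window i covers [i*step, i*step + width); a tag at position p is counted
    by every window containing p. Windows tile [0, chrom_length): the last
    window may extend past the chromosome end, but tags may not.
    """
    if library.total_tags == 0:
        raise ValueError(f"empty tag library {library.sample_id!r}")
    missing = set(library.positions) - set(chrom_lengths)
    if missing:
        raise ValueError(
            f"{library.sample_id}: tag chromosomes missing from chrom_lengths: "
            + ", ".join(sorted(missing)))
    tracks = {}
    for chrom, length in chrom_lengths.items():
        n_win = -(-length // step)  # ceil: starts 0, step, ..., all < length
        pos = library.positions.get(chrom, np.empty(0, dtype=np.int64))
        if pos.size and pos.max() >= length:
            raise ValueError(f"{library.sample_id}: tag beyond end of {chrom}")
        # window starts containing p: s in (p - width, p], s multiple of step
        i_min = np.maximum(0, -((-(pos - width + 1)) // step))
        i_max = pos // step  # < n_win since pos < length <= n_win*step
        delta = np.zeros(n_win + 1)
        np.add.at(delta, i_min, 1.0)
        np.add.at(delta, i_max + 1, -1.0)
        tracks[chrom] = WindowTrack(chrom, np.cumsum(delta[:-1]), width, step)
    return tracks


def normalize_by_library(track: WindowTrack, total_tags: int) -> WindowTrack:
    """Divide window counts by the library's total tag count."""
    if total_tags <= 0:
        raise ValueError("total_tags must be positive")
    return WindowTrack(track.chrom, track.values / total_tags,
                       track.width, track.step, track.start0)


def subtract_input(test: WindowTrack, control: WindowTrack) -> WindowTrack:
    """Window-wise test minus input; values may be negative."""
    if not test.same_grid(control):
        raise ValueError(
            f"window grid mismatch between {test.chrom} test and input tracks")
    return WindowTrack(test.chrom, test.values - control.values,
                       test.width, test.step, test.start0)


def log2_transform(track: WindowTrack, epsilon: float = DEFAULT_EPSILON) -> WindowTrack:
    """log2(max(v, 0) + epsilon): monotone, with depleted windows at a common floor."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    return WindowTrack(track.chrom, np.log2(np.maximum(track.values, 0.0) + epsilon),
                       track.width, track.step, track.start0)


def average_tss_window(tracks: dict[str, WindowTrack], genes: list[GeneModel],
                       flank: int = DEFAULT_FLANK,
                       ) -> tuple[pd.Series, list[str]]:
    """Per-gene mean of window values whose centers lie in [TSS-flank, TSS+flank].

    Returns (scores indexed by gene_id, list of genes with no covered window
    center or whose chromosome has no track).
    """
    scores: dict[str, float] = {}
    missing: list[str] = []
    for gene in genes:
        track = tracks.get(gene.chrom)
        if track is None:
            missing.append(gene.gene_id)
            continue
        half = track.width / 2
        # centers c_i = start0 + i*step + width/2 with tss-flank <= c_i <= tss+flank
        lo = gene.tss - flank - half - track.start0
        hi = gene.tss + flank - half - track.start0
        i_min = max(0, math.ceil(lo / track.step))
        i_max = min(track.values.size - 1, math.floor(hi / track.step))
        if i_min > i_max:
            missing.append(gene.gene_id)
            continue
        scores[gene.gene_id] = float(track.values[i_min:i_max + 1].mean())
    return pd.Series(scores, name="score"), missing


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force identical value distributions across columns, preserving ranks.

    The reference distribution is the row-wise mean of the column-sorted
    matrix; the rank-i value of each column is replaced by reference value i.
    Tied values within a column receive the mean of the reference values over
    the tied rank span, so within-column rank order (with ties) is preserved
    and the transform is idempotent.
    """
    if matrix.isna().to_numpy().any():
        raise ValueError("missing values not allowed in quantile normalization")
    if matrix.shape[1] < 2:
        warnings.warn("quantile normalization of a single column is the identity")
        return matrix.copy()
    vals = matrix.to_numpy(dtype=float)
    order = np.argsort(vals, axis=0, kind="stable")
    ref = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        srt = order[:, j]
        col_sorted = vals[srt, j]
        grp = np.concatenate([[0], np.cumsum(col_sorted[1:] != col_sorted[:-1])])
        grp_mean = np.bincount(grp, weights=ref) / np.bincount(grp)
        out[srt, j] = grp_mean[grp]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def compute_histone_matrix(pairs: list[tuple[TagLibrary, TagLibrary]],
                           genes: list[GeneModel],
                           chrom_lengths: dict[str, int],
                           width: int = DEFAULT_WIDTH, step: int = DEFAULT_STEP,
                           flank: int = DEFAULT_FLANK,
                           epsilon: float = DEFAULT_EPSILON,
                           ) -> tuple[TssSignalMatrix, TssSignalMatrix]:
    """Run the five-step scoring for each (test, input) pair.

    Returns (normalized, raw) matrices; a gene is kept only if it has a score
    in every sample, otherwise it is listed in ``missing_genes``.
    """
    if not pairs:
        raise ValueError("no (test, input) library pairs given")
    columns: dict[str, pd.Series] = {}
    meta_rows = []
    missing_all: set[str] = set()
    for test, control in pairs:
        if test.sample_id in columns:
            raise ValueError(f"duplicate test sample id {test.sample_id!r}")
        test_tracks = count_window_tags(test, chrom_lengths, width, step)
        ctrl_tracks = count_window_tags(control, chrom_lengths, width, step)
        tracks = {}
        for chrom in chrom_lengths:
            t = normalize_by_library(test_tracks[chrom], test.total_tags)
            c = normalize_by_library(ctrl_tracks[chrom], control.total_tags)
            tracks[chrom] = log2_transform(subtract_input(t, c), epsilon)
        scores, missing = average_tss_window(tracks, genes, flank)
        columns[test.sample_id] = scores
        missing_all.update(missing)
        meta_rows.append({"sample_id": test.sample_id, "antibody": test.antibody,
                          "fraction": test.fraction, "stage": test.stage})
    gene_order = [g.gene_id for g in genes if g.gene_id not in missing_all]
    raw_values = pd.DataFrame({sid: col.reindex(gene_order) for sid, col in columns.items()})
    raw_values.index.name = "gene_id"
    samples = pd.DataFrame(meta_rows).set_index("sample_id")
    missing_list = sorted(missing_all)
    raw = TssSignalMatrix(raw_values, samples, normalized=False,
                          flank=flank, missing_genes=missing_list)
    norm_values = (quantile_normalize(raw_values) if raw_values.shape[1] >= 2
                   else raw_values.copy())
    norm = TssSignalMatrix(norm_values, samples.copy(), normalized=True,
                           flank=flank, missing_genes=missing_list)
    return norm, raw
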