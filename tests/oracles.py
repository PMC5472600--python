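"""Independent brute-force reference implementations used only by tests.

Each oracle recomputes a pipeline quantity by direct enumeration or a
textbook formula, sharing no code with the package internals it checks.
"""
from __future__ import annotations

import numpy as np
import pandas as pd


def brute_gene_score(test_pos, test_total, ctrl_pos, ctrl_total, tss,
                     chrom_length, width=1050, step=50, flank=5000,
                     epsilon=1e-9):
    """One gene's histone score by direct window enumeration."""
    test_pos = np.asarray(test_pos)
    ctrl_pos = np.asarray(ctrl_pos)
    vals = []
    s = 0
    while s < chrom_length:
        center = s + width / 2
        if tss - flank <= center <= tss + flank:
            t = np.count_nonzero((test_pos >= s) & (test_pos < s + width))
            c = np.count_nonzero((ctrl_pos >= s) & (ctrl_pos < s + width))
            diff = t / test_total - c / ctrl_total
            vals.append(np.log2(max(diff, 0.0) + epsilon))
        s += step
    if not vals:
        return None
    return float(np.mean(vals))


def naive_quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Quantile normalization via an explicit value->reference map per column."""
    ref = np.mean(np.column_stack([np.sort(df[c].to_numpy()) for c in df.columns]),
                  axis=1)
    out = {}
    for c in df.columns:
        col = df[c].to_numpy()
        uniq, counts = np.unique(col, return_counts=True)
        ends = counts.cumsum()
        starts = ends - counts
        vmap = {u: ref[s:e].mean() for u, s, e in zip(uniq, starts, ends)}
        out[c] = np.array([vmap[v] for v in col])
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def brute_histone_matrix(pairs, genes, chrom_lengths, width=1050, step=50,
                         flank=5000, epsilon=1e-9) -> pd.DataFrame:
    """Full scoring chain by enumeration, then naive quantile normalization."""
    empty = np.empty(0, dtype=np.int64)
    columns = {}
    missing = set()
    for test, ctrl in pairs:
        scores = {}
        for g in genes:
            if g.chrom not in chrom_lengths:
                missing.add(g.gene_id)
                continue
            score = brute_gene_score(
                test.positions.get(g.chrom, empty), test.total_tags,
                ctrl.positions.get(g.chrom, empty), ctrl.total_tags,
                g.tss, chrom_lengths[g.chrom], width, step, flank, epsilon)
            if score is None:
                missing.add(g.gene_id)
            else:
                scores[g.gene_id] = score
        columns[test.sample_id] = scores
    order = [g.gene_id for g in genes if g.gene_id not in missing]
    raw = pd.DataFrame({sid: pd.Series(col).reindex(order)
                        for sid, col in columns.items()})
    if raw.shape[1] < 2:
        return raw
    return naive_quantile_normalize(raw)


def greedy_ward_partition(X: np.ndarray, k: int) -> set[frozenset]:
    """Agglomerate by always merging the pair with minimal Ward cost."""
    clusters = [[i] for i in range(len(X))]
    while len(clusters) > k:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                A, B = X[clusters[a]], X[clusters[b]]
                na, nb = len(A), len(B)
                cost = na * nb / (na + nb) * ((A.mean(0) - B.mean(0)) ** 2).sum()
                if best is None or cost < best[0]:
                    best = (cost, a, b)
        _, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return {frozenset(c) for c in clusters}


def brute_select_representatives(values: pd.DataFrame, assignment: dict,
                                 sum_samples, modes: dict, top_n_sum=18,
                                 top_n_select=3, combine="sum") -> dict:
    """Representative selection via explicit sort-twice recomputation."""
    out = {}
    for label in sorted(set(assignment.values()), key=str):
        members = sorted(g for g, lab in assignment.items()
                         if lab == label and g in values.index)
        scored = []
        for g in members:
            row = values.loc[g, sum_samples]
            s = float(row.sum())
            d_parts = [(float(row.iloc[i]) - float(row.iloc[i + 1])) ** 2
                       for i in range(0, len(sum_samples), 2)]
            d = sum(d_parts) if combine == "sum" else max(d_parts)
            scored.append((g, s, d))
        pool = sorted(scored, key=lambda t: (-t[1], t[0]))[:top_n_sum]
        mode = modes.get(str(label), "smallest_diff")
        if mode == "smallest_diff":
            final = sorted(pool, key=lambda t: (t[2], t[0]))
        else:
            final = sorted(pool, key=lambda t: (-t[2], t[0]))
        out[str(label)] = [g for g, _, _ in final[:top_n_select]]
    return out


def pooled_t(a, b):
    """Textbook pooled-variance two-sample t statistic and df."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    return t, na + nb - 2
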