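"""Readers and writers for the external file formats.

Accepted inputs: BED6+ gene annotation (biotype in column 7, optional
category in column 8), a gene-line GTF subset, BED3/BED6 tag files and
TSV matrices with a header row. All outputs are TSV. Internal coordinates
are 0-based half-open; GTF records are converted at read time.
"""
from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .models import GeneModel, TagLibrary

_FLOAT_FMT = "%.12g"  # >= 10 significant digits for lossless round-trips


class FormatError(ValueError):
    """Malformed input file; message names the offending line."""


def _parse_gtf_attributes(attr_field: str) -> dict[str, str]:
    out = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def read_gene_annotation(path, dialect: str = "bed6plus") -> list[GeneModel]:
    """Read a gene annotation file into GeneModel records.

    ``bed6plus``: chrom, start, end, gene_id, score, strand, biotype[, category].
    ``gtf_subset``: gene feature lines only; gene_id and (gene_)biotype taken
    from the attribute column; 1-based inclusive coordinates converted to
    0-based half-open.
    """
    if dialect not in ("bed6plus", "gtf_subset"):
        raise ValueError(f"unknown dialect {dialect!r}")
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if dialect == "bed6plus":
                    if len(fields) < 7:
                        raise ValueError("expected >= 7 columns")
                    chrom, start, end, gene_id, _score, strand = fields[:6]
                    biotype = fields[6]
                    category = fields[7] if len(fields) > 7 and fields[7] not in (".", "") else None
                    gene = GeneModel(gene_id, chrom, strand, int(start), int(end),
                                     biotype, category)
                else:
                    if len(fields) < 9:
                        raise ValueError("expected 9 GTF columns")
                    chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
                    if feature != "gene":
                        continue
                    a = _parse_gtf_attributes(attrs)
                    gene_id = a.get("gene_id")
                    if gene_id is None:
                        raise ValueError("missing gene_id attribute")
                    biotype = a.get("gene_biotype", a.get("biotype", "protein_coding"))
                    gene = GeneModel(gene_id, chrom, strand,
                                     int(start) - 1, int(end),  # 1-based inclusive -> 0-based half-open
                                     biotype, a.get("category"))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if gene.gene_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene_id {gene.gene_id!r}")
            seen.add(gene.gene_id)
            genes.append(gene)
    return genes


def write_gene_annotation(genes: list[GeneModel], path) -> None:
    """Write genes as BED6+ (biotype column 7, category column 8)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write("\t".join([
                g.chrom, str(g.tx_start), str(g.tx_end), g.gene_id, "0",
                g.strand, g.biotype, g.category if g.category else ".",
            ]) + "\n")


def read_tag_bed(path, sample_id: str | None = None, antibody: str = "input",
                 fraction: str = "", stage: str = "") -> TagLibrary:
    """Read a BED3/BED6 tag file; each line becomes one tag.

    The tag position is the 5' end of the read interval: the interval start
    for + (or strandless) records, end-1 for - records.
    """
    positions: dict[str, list[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0:
                raise FormatError(f"{path}:{lineno}: negative coordinate")
            if end <= start:
                raise FormatError(f"{path}:{lineno}: end <= start")
            strand = fields[5] if len(fields) > 5 else "+"
            pos = start if strand != "-" else end - 1
            positions.setdefault(chrom, []).append(pos)
    if sample_id is None:
        sample_id = Path(path).stem
    return TagLibrary(sample_id,
                      {c: np.asarray(p, dtype=np.int64) for c, p in positions.items()},
                      antibody=antibody, fraction=fraction, stage=stage)


def write_tag_bed(library: TagLibrary, path, read_length: int = 36) -> None:
    """Write tags as stranded BED6 intervals of ``read_length`` on + strand."""
    with open(path, "w") as fh:
        for chrom in library.chroms:
            for p in library.positions[chrom]:
                fh.write(f"{chrom}\t{p}\t{p + read_length}\t.\t0\t+\n")


def read_expression_tsv(path) -> pd.DataFrame:
    """Read a gene x sample TSV (header row of sample ids, first column gene_id).

    Missing or non-numeric cells are an error naming the row and column.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene_id {dup!r}")
    if df.columns.has_duplicates:
        raise FormatError(f"{path}: duplicate sample ids in header")
    out = pd.DataFrame(index=df.index.astype(str), columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise FormatError(
                f"{path}: non-numeric or missing value at gene {gene!r}, sample {col!r}")
        out[col] = converted.to_numpy(dtype=float)
    out.index.name = "gene_id"
    return out


def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    """Write a labelled gene x sample matrix as TSV (lossless at 12 sig. digits)."""
    matrix = matrix.copy()
    matrix.index.name = matrix.index.name or "gene_id"
    matrix.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_category_table(path) -> dict[str, str]:
    """Read a 2-column gene_id -> category TSV (header optional)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if lineno == 1 and row[0].lower() in ("gene_id", "gene"):
                continue
            if len(row) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            out[row[0]] = row[1]
    return out


def write_category_table(categories: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tcategory\n")
        for gene, cat in sorted(categories.items()):
            fh.write(f"{gene}\t{cat}\n")
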