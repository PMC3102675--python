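"""Readers and writers for the small text formats the pipeline speaks.

Internal coordinates are 0-based half-open everywhere; conversions happen
only here. BED is consumed/produced 0-based half-open; GFF-like
annotations are 1-based inclusive on disk and converted on read. Malformed
lines raise :class:`~rechip.errors.ParseError` carrying the line number;
reads beyond their chromosome are not rejected here but by the counting
stage, which reports a dropped-read count.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd

from .errors import ParseError


def read_bed(path) -> pd.DataFrame:
    """Read aligned reads from BED (3+ columns; strand from column 6).

    Returns ``chrom, start, strand`` with ``start`` the record's leftmost
    (0-based) coordinate, used downstream as the read's 5' anchor.
    """
    chroms, starts, strands = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError("BED line has fewer than 3 columns", str(path), lineno)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as e:
                raise ParseError(f"non-integer coordinate: {e}", str(path), lineno) from None
            if start < 0 or start > end:
                raise ParseError(f"invalid interval [{start}, {end})", str(path), lineno)
            chroms.append(fields[0])
            starts.append(start)
            strands.append(fields[5] if len(fields) >= 6 else "+")
    return pd.DataFrame({"chrom": chroms, "start": starts, "strand": strands})


def write_bed(reads: pd.DataFrame, path, read_length: int = 36) -> None:
    """Write reads as BED6: chrom, start, start+read_length, name, score, strand."""
    with open(path, "w") as fh:
        for i, row in enumerate(reads.itertuples()):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.start + read_length}\t"
                f"read_{i}\t0\t{row.strand}\n"
            )


def read_chrom_sizes(path) -> pd.DataFrame:
    """UCSC-style chrom.sizes: two tab-separated columns, no header."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError("chrom.sizes line needs 2 columns", str(path), lineno)
            try:
                rows.append((fields[0], int(fields[1])))
            except ValueError:
                raise ParseError("non-integer chromosome size", str(path), lineno) from None
    return pd.DataFrame(rows, columns=["chrom", "size"])


def write_chrom_sizes(sizes: pd.DataFrame, path) -> None:
    sizes[["chrom", "size"]].to_csv(path, sep="\t", header=False, index=False)


def read_annotation(path, fmt: str = "tsv") -> pd.DataFrame:
    """Gene annotation: ``gene_id, chrom, tss, strand``.

    ``fmt="tsv"``: headered table with 0-based ``tss``. ``fmt="gff"``:
    GFF-like 9-column records (1-based inclusive); the TSS is the start of
    a ``+`` feature or the end of a ``-`` feature, converted to 0-based.
    """
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t")
        missing = {"gene_id", "chrom", "tss", "strand"} - set(df.columns)
        if missing:
            raise ParseError(f"annotation lacks columns {sorted(missing)}", str(path))
        return df
    if fmt != "gff":
        raise ValueError(f"unknown annotation format {fmt!r}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise ParseError("GFF line has fewer than 9 columns", str(path), lineno)
            try:
                start1, end1 = int(f[3]), int(f[4])
            except ValueError:
                raise ParseError("non-integer GFF coordinate", str(path), lineno) from None
            if start1 < 1 or end1 < start1:
                raise ParseError(f"invalid GFF interval {start1}..{end1}", str(path), lineno)
            strand = f[6]
            tss = start1 - 1 if strand != "-" else end1 - 1
            gene_id = f[8]
            for token in f[8].split(";"):
                token = token.strip()
                if token.startswith(("ID=", "gene_id=")):
                    gene_id = token.split("=", 1)[1]
                    break
            rows.append((gene_id, f[0], tss, strand))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])


def read_mapability(path) -> pd.DataFrame:
    """Per-window mapability keyed by window start (headered TSV)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"chrom", "start", "mapability"} - set(df.columns)
    if missing:
        raise ParseError(f"mapability track lacks columns {sorted(missing)}", str(path))
    return df


def read_table(path) -> pd.DataFrame:
    """Generic headered TSV (probe tables, peak tables, group maps)."""
    return pd.read_csv(path, sep="\t")


def read_expression_matrix(path) -> pd.DataFrame:
    """miRNA x sample intensity matrix; first column is the miRNA id."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_group_map(path) -> dict:
    """Two-column sample→group TSV into ``{group: [samples]}``."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ParseError("group map needs columns sample, group", str(path))
    sample_col, group_col = df.columns[:2]
    groups: dict = {}
    for row in df.itertuples(index=False):
        groups.setdefault(getattr(row, group_col), []).append(getattr(row, sample_col))
    return groups


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
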