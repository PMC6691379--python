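"""Readers and writers for the external formats the pipeline consumes.

All genomic coordinates are 0-based half-open internally (BED convention).
GFF3 coordinates are converted at this boundary and nowhere else.

Peak collections are plain :class:`pandas.DataFrame` objects with columns
``chrom, start, end, name, score, strand, summit, factor, condition``
(``summit`` is an absolute genomic coordinate).  TSS annotations use columns
``gene_id, chrom, tss, strand``.
"""

from __future__ import annotations

import logging
import math
import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PEAK_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "summit", "factor", "condition",
]
TSS_COLUMNS = ["gene_id", "chrom", "tss", "strand"]


class FormatError(ValueError):
    """Raised for malformed input files; message names the offending line."""


# ---------------------------------------------------------------------------
# peaks (BED6 / ENCODE narrowPeak)
# ---------------------------------------------------------------------------

def read_peaks(path: str | os.PathLike, factor: str, condition: str,
               min_score: float | None = None) -> pd.DataFrame:
    """Read a BED6 or ENCODE narrowPeak file into a peak table.

    narrowPeak column 10 is the summit offset from ``start``; an offset of
    -1 (or a BED6 file, which has no summit column) falls back to the
    interval midpoint ``floor((start + end) / 2)``.

    Parameters
    ----------
    path
        BED6 (6 columns) or narrowPeak (10 columns) file.
    factor, condition
        Labels attached to every peak (e.g. ``"HIF1A"``, ``"hypoxia"``).
    min_score
        Optional score filter; peaks with ``score < min_score`` are dropped.
        Peak callers were run upstream, so by default every record is kept.

    Returns
    -------
    pandas.DataFrame
        Peaks sorted by ``(chrom, start)``.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) not in (6, 10):
                raise FormatError(
                    f"{path}: line {lineno}: expected 6 (BED6) or 10 "
                    f"(narrowPeak) columns, got {len(fields)}")
            try:
                chrom = fields[0]
                start = int(fields[1])
                end = int(fields[2])
                name = fields[3]
                score = float(fields[4]) if fields[4] not in (".", "") else math.nan
                strand = fields[5]
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
            if not chrom:
                raise FormatError(f"{path}: line {lineno}: empty chromosome")
            if start >= end:
                raise FormatError(
                    f"{path}: line {lineno}: start {start} >= end {end}")
            if len(fields) == 10:
                try:
                    offset = int(float(fields[9]))
                except ValueError as exc:
                    raise FormatError(f"{path}: line {lineno}: {exc}") from None
            else:
                offset = -1
            summit = start + offset if offset >= 0 else (start + end) // 2
            if not (start <= summit < end):
                raise FormatError(
                    f"{path}: line {lineno}: summit {summit} outside "
                    f"[{start}, {end})")
            rows.append((chrom, start, end, name, score, strand, summit))
    df = pd.DataFrame(rows, columns=PEAK_COLUMNS[:7])
    if min_score is not None:
        kept = df["score"] >= min_score
        logger.info("read_peaks(%s): score filter dropped %d/%d peaks",
                    path, int((~kept).sum()), len(df))
        df = df[kept]
    df["factor"] = factor
    df["condition"] = condition
    df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return df


def write_peaks(peaks: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a peak table as ENCODE narrowPeak (summit stored in column 10)."""
    with open(path, "w") as fh:
        for row in peaks.itertuples(index=False):
            score = 0 if pd.isna(row.score) else row.score
            fh.write("\t".join(str(v) for v in (
                row.chrom, row.start, row.end, row.name,
                int(score) if float(score).is_integer() else score,
                row.strand, 0, -1, -1, row.summit - row.start)) + "\n")


# ---------------------------------------------------------------------------
# TSS annotation (GFF3 / 4-column TSV)
# ---------------------------------------------------------------------------

def _gff3_attribute(attrs: str, keys: Sequence[str]) -> str | None:
    for part in attrs.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            if k.strip() in keys:
                return v.strip()
    return None


def read_tss(path: str | os.PathLike, feature_type: str = "gene") -> pd.DataFrame:
    """Read a TSS annotation from GFF3 or a 4-column TSV.

    GFF3 rows of ``feature_type`` are used; the TSS is the 1-based feature
    start for "+" genes and the feature end for "-" genes, converted to a
    0-based coordinate.  The TSV form (``gene_id  chrom  tss  strand``) is
    assumed 0-based already.  Duplicate gene ids and unknown strand symbols
    raise :class:`FormatError`.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 9:  # GFF3
                if fields[2] != feature_type:
                    continue
                chrom, strand = fields[0], fields[6]
                if strand not in ("+", "-"):
                    raise FormatError(
                        f"{path}: line {lineno}: unknown strand {strand!r}")
                try:
                    start1, end1 = int(fields[3]), int(fields[4])
                except ValueError as exc:
                    raise FormatError(f"{path}: line {lineno}: {exc}") from None
                gene_id = _gff3_attribute(fields[8], ("ID", "gene_id", "Name"))
                if gene_id is None:
                    raise FormatError(
                        f"{path}: line {lineno}: no ID/gene_id attribute")
                tss = start1 - 1 if strand == "+" else end1 - 1
            elif len(fields) == 4:
                if lineno == 1 and fields[0] == "gene_id":
                    continue  # optional header
                gene_id, chrom, strand = fields[0], fields[1], fields[3]
                if strand not in ("+", "-"):
                    raise FormatError(
                        f"{path}: line {lineno}: unknown strand {strand!r}")
                try:
                    tss = int(fields[2])
                except ValueError as exc:
                    raise FormatError(f"{path}: line {lineno}: {exc}") from None
            else:
                raise FormatError(
                    f"{path}: line {lineno}: expected 9 (GFF3) or 4 (TSV) "
                    f"columns, got {len(fields)}")
            rows.append((gene_id, chrom, tss, strand))
    df = pd.DataFrame(rows, columns=TSS_COLUMNS)
    dup = df["gene_id"].duplicated()
    if dup.any():
        raise FormatError(
            f"{path}: duplicate gene_id(s): "
            f"{sorted(df.loc[dup, 'gene_id'].unique())[:5]}")
    return df.reset_index(drop=True)


def write_tss(annotation: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a TSS annotation as the 0-based 4-column TSV form."""
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\ttss\tstrand\n")
        for row in annotation.itertuples(index=False):
            fh.write(f"{row.gene_id}\t{row.chrom}\t{row.tss}\t{row.strand}\n")


# ---------------------------------------------------------------------------
# expression matrices, labels, gene lists
# ---------------------------------------------------------------------------

def read_expression(path: str | os.PathLike,
                    labels_path: str | os.PathLike | None = None,
                    ) -> tuple[pd.DataFrame, pd.Series | None]:
    """Read a genes x samples TSV matrix (and optionally sample labels).

    The first column holds gene ids and the header row sample ids.  Genes
    with any non-numeric cell are dropped and the count logged.  When
    ``labels_path`` is given, every matrix sample must appear in it.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        logger.warning("read_expression(%s): rejected %d gene(s) with "
                       "non-numeric cells", path, int(bad.sum()))
    matrix = numeric.loc[~bad].astype(float)
    matrix.index.name = "gene_id"
    labels = None
    if labels_path is not None:
        labels = read_labels(labels_path)
        missing = [s for s in matrix.columns if s not in labels.index]
        if missing:
            raise FormatError(
                f"{labels_path}: sample(s) missing from label file: {missing}")
        labels = labels.loc[list(matrix.columns)]
    return matrix, labels


def write_expression(matrix: pd.DataFrame, path: str | os.PathLike) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def read_labels(path: str | os.PathLike) -> pd.Series:
    """Read a two-column ``sample<TAB>group`` file (no header)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[1]:
                raise FormatError(
                    f"{path}: line {lineno}: expected 'sample<TAB>group'")
            rows.append(fields)
    s = pd.Series({k: v for k, v in rows}, name="group")
    s.index.name = "sample"
    return s


def write_labels(labels: pd.Series, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for sample, group in labels.items():
            fh.write(f"{sample}\t{group}\n")


def read_gene_list(path: str | os.PathLike) -> list[str]:
    """One gene symbol per line; '#' lines (incl. provenance headers) skipped."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line)
    return genes


def write_gene_list(genes: Iterable[str], path: str | os.PathLike,
                    provenance: str | None = None) -> None:
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# provenance: {provenance}\n")
        for g in genes:
            fh.write(f"{g}\n")


# ---------------------------------------------------------------------------
# survival tables, well-count tables, truth records
# ---------------------------------------------------------------------------

def read_survival(path: str | os.PathLike) -> pd.DataFrame:
    """Read a ``patient  time  event`` TSV (header required)."""
    df = pd.read_csv(path, sep="\t")
    required = {"patient", "time", "event"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    if (df["time"] <= 0).any():
        raise FormatError(f"{path}: non-positive survival time")
    if not df["event"].isin((0, 1)).all():
        raise FormatError(f"{path}: event must be 0 or 1")
    return df


def write_survival(table: pd.DataFrame, path: str | os.PathLike) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_well_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a limiting-dilution ``dose  wells  negative`` TSV."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"dose", "wells", "negative"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    if (df["negative"] > df["wells"]).any() or (df["dose"] < 0).any():
        raise FormatError(f"{path}: inconsistent well counts")
    return df


def write_well_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_truth(truth: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a simulator truth record (marked with a ``#truth`` header)."""
    with open(path, "w") as fh:
        fh.write("#truth\n")
        truth.to_csv(fh, sep="\t", index=False)


def read_truth(path: str | os.PathLike) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#truth"):
            raise FormatError(f"{path}: not a truth record")
        return pd.read_csv(fh, sep="\t")
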