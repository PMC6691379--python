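"""Strand-aware assignment of peaks to genes around the TSS.

A peak belongs to a gene when the signed, transcription-direction distance
of its summit from the gene's TSS falls inside the closed window
``[lower, upper]`` (default -2 kb .. +6 kb).  Negative distances are
upstream of the TSS.  Membership is decided by the summit, not by interval
overlap; both the orientation and the summit rule can be switched off for
sensitivity analyses.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ASSIGNMENT_COLUMNS = ["gene_id", "peak_index", "factor", "condition",
                      "chrom", "summit", "peak_start", "distance"]


def assign_peaks(peaks: pd.DataFrame, annotation: pd.DataFrame,
                 tss_window: tuple[int, int] = (-2000, 6000),
                 oriented: bool = True) -> pd.DataFrame:
    """Assign every peak summit to every gene whose TSS window contains it.

    Parameters
    ----------
    peaks
        Peak table (see :mod:`hifwnt.io`), sorted by ``(chrom, start)``.
    annotation
        TSS table with ``gene_id, chrom, tss, strand``.
    tss_window
        Closed signed window around the TSS, in transcription-direction bp.
    oriented
        When False, the window is applied in genomic coordinates for every
        gene regardless of strand (distances still carry the strand sign
        convention of +1).

    Returns
    -------
    pandas.DataFrame
        One row per (gene, peak) pair inside the window; a peak may assign
        to several genes and a gene may collect several peaks.
    """
    lo, hi = tss_window
    if not lo < hi:
        raise ValueError(f"tss_window lower {lo} must be < upper {hi}")
    missing = set(peaks["chrom"]) - set(annotation["chrom"])
    if missing:
        logger.warning("assign_peaks: %d peak(s) on chromosome(s) absent "
                       "from the annotation skipped: %s",
                       int(peaks["chrom"].isin(missing).sum()), sorted(missing))
    out = []
    for chrom, genes in annotation.groupby("chrom"):
        sub = peaks[peaks["chrom"] == chrom]
        if sub.empty:
            continue
        summits = sub["summit"].to_numpy()
        order = np.argsort(summits, kind="stable")
        s_sorted = summits[order]
        idx_sorted = sub.index.to_numpy()[order]
        starts = sub["peak_start"].to_numpy() if "peak_start" in sub else sub["start"].to_numpy()
        starts_sorted = starts[order]
        factors = sub["factor"].to_numpy()[order]
        conditions = sub["condition"].to_numpy()[order]
        for g in genes.itertuples(index=False):
            sign = -1 if (oriented and g.strand == "-") else 1
            if sign == 1:
                g_lo, g_hi = g.tss + lo, g.tss + hi
            else:
                g_lo, g_hi = g.tss - hi, g.tss - lo
            i = np.searchsorted(s_sorted, g_lo, side="left")
            j = np.searchsorted(s_sorted, g_hi, side="right")
            strand_sign = -1 if g.strand == "-" else 1
            for k in range(i, j):
                dist = int((s_sorted[k] - g.tss) * strand_sign)
                out.append((g.gene_id, int(idx_sorted[k]), factors[k],
                            conditions[k], chrom, int(s_sorted[k]),
                            int(starts_sorted[k]), dist))
    return pd.DataFrame(out, columns=ASSIGNMENT_COLUMNS)


def nearest_assignment_per_gene(assignments: pd.DataFrame) -> pd.DataFrame:
    """Keep one representative assignment per gene.

    The assignment with minimal ``|distance|`` wins; ties break toward the
    more upstream peak (smaller signed distance), then by peak start.
    """
    if assignments.empty:
        return assignments.copy()
    ranked = assignments.assign(_abs=assignments["distance"].abs())
    ranked = ranked.sort_values(["gene_id", "_abs", "distance", "peak_start"],
                                kind="mergesort")
    best = ranked.groupby("gene_id", sort=True).head(1).drop(columns="_abs")
    return best.reset_index(drop=True)


def bound_gene_set(assignments: pd.DataFrame) -> set[str]:
    """Genes with at least one assigned peak."""
    return set(assignments["gene_id"]) if len(assignments) else set()
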