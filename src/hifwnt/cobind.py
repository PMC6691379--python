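"""Two-factor co-localization and binding-window architecture.

The analysis asks how two transcription factors arrange themselves around
the genes they jointly occupy: a 2-D density of their TSS distances, a
composite (cumulative) summit profile per factor around shared anchor
points, and a call of the composite architecture — the window where all
factors sit together plus the flanks where exactly one of them binds.

Anchoring matters.  With a single representative summit per factor and
anchors taken as the per-gene mean of the two summits, the two factors'
offsets are exact negatives of each other gene by gene, so their composite
profiles are mirror images and an asymmetric architecture cannot be
observed.  ``anchor_positions`` (summit mean) is therefore suited to
symmetric questions only; architecture calls should anchor on an external
reference — ``tss_anchor_positions`` uses the annotated TSS.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import nearest_assignment_per_gene

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# co-bound genes and their joint TSS-distance geometry
# ---------------------------------------------------------------------------

def cobound_genes(assign_a: pd.DataFrame, assign_b: pd.DataFrame) -> pd.DataFrame:
    """Genes bound by both factors, with representative distances/summits.

    Returns a frame with columns ``gene_id, d_a, d_b, summit_a, summit_b,
    chrom`` where the representative peak per factor is the nearest
    assignment (see :func:`hifwnt.annotate.nearest_assignment_per_gene`).
    """
    rep_a = nearest_assignment_per_gene(assign_a)
    rep_b = nearest_assignment_per_gene(assign_b)
    merged = rep_a.merge(rep_b, on="gene_id", suffixes=("_a", "_b"))
    return pd.DataFrame({
        "gene_id": merged["gene_id"],
        "chrom": merged["chrom_a"],
        "d_a": merged["distance_a"],
        "d_b": merged["distance_b"],
        "summit_a": merged["summit_a"],
        "summit_b": merged["summit_b"],
    })


@dataclasses.dataclass
class DensityGrid:
    """2-D histogram of paired TSS distances with contour levels."""

    bin_edges_x: np.ndarray
    bin_edges_y: np.ndarray
    counts: np.ndarray  # shape (nx, ny), integer
    contour_levels: dict[float, float]

    @property
    def n_pairs(self) -> int:
        return int(self.counts.sum())


def localization_density(pairs: pd.DataFrame, binwidth: int,
                         window: tuple[int, int],
                         contour_quantiles: Sequence[float] = (0.5, 0.75, 0.9),
                         ) -> DensityGrid:
    """Joint histogram of (d_a, d_b) over ``window x window``.

    Contour levels are count quantiles over the occupied (non-zero) cells;
    pairs outside the window are dropped (the callers pass the same window
    used for assignment, so nothing is lost in the standard chain).
    """
    lo, hi = window
    edges = np.arange(lo, hi + binwidth, binwidth, dtype=float)
    inside = ((pairs["d_a"] >= lo) & (pairs["d_a"] <= hi)
              & (pairs["d_b"] >= lo) & (pairs["d_b"] <= hi))
    counts, ex, ey = np.histogram2d(
        pairs.loc[inside, "d_a"], pairs.loc[inside, "d_b"], bins=(edges, edges))
    counts = counts.astype(int)
    occupied = counts[counts > 0]
    levels = {q: (float(np.quantile(occupied, q)) if occupied.size else 0.0)
              for q in contour_quantiles}
    return DensityGrid(ex, ey, counts, levels)


def anchor_positions(pairs: pd.DataFrame) -> pd.Series:
    """Per-gene anchor: mean of the two representative summits.

    Rounded half-down (floor of the .5 midpoint).  See the module note on
    the mirror-symmetry limitation of this anchor choice.
    """
    anchors = (pairs["summit_a"] + pairs["summit_b"]) // 2
    return pd.Series(anchors.to_numpy(), index=pairs["gene_id"].to_numpy(),
                     name="anchor")


def tss_anchor_positions(genes: Sequence[str],
                         annotation: pd.DataFrame) -> pd.Series:
    """Per-gene anchor at the annotated TSS (external reference point)."""
    tss = annotation.set_index("gene_id")["tss"]
    return tss.loc[list(genes)].rename("anchor")


# ---------------------------------------------------------------------------
# composite profiles
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CompositeProfile:
    """Mean summit count per anchor per offset bin for one factor."""

    factor: str
    bin_edges: np.ndarray  # signed bp, uniform width, symmetric about 0
    values: np.ndarray     # len(bin_edges) - 1, summits per anchor per bin
    n_anchors: int

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    @property
    def binwidth(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


def composite_profiles(peaks_by_factor: Mapping[str, pd.DataFrame],
                       anchors: pd.Series, annotation: pd.DataFrame,
                       halfwidth: int = 400, binwidth: int = 10,
                       ) -> dict[str, CompositeProfile]:
    """Cumulative summit profiles of each factor around shared anchors.

    For each anchor, every summit of the factor within ``[-halfwidth,
    +halfwidth)`` contributes at its binned transcription-direction offset;
    bin values are averaged over anchors.  Factors beyond the pair that
    defined the anchors (e.g. a third factor mapped in another condition)
    may be profiled passively on the same anchors.
    """
    if halfwidth % binwidth != 0:
        raise ValueError("halfwidth must be a multiple of binwidth")
    edges = np.arange(-halfwidth, halfwidth + binwidth, binwidth, dtype=float)
    meta = annotation.set_index("gene_id")
    genes = anchors.index.to_numpy()
    strands = meta.loc[genes, "strand"].to_numpy()
    chroms = meta.loc[genes, "chrom"].to_numpy()
    signs = np.where(strands == "-", -1, 1)
    pos = anchors.to_numpy()

    profiles = {}
    for factor, peaks in peaks_by_factor.items():
        offsets_all = []
        for chrom in np.unique(chroms):
            summits = np.sort(peaks.loc[peaks["chrom"] == chrom, "summit"].to_numpy())
            sel = chroms == chrom
            for a, sg in zip(pos[sel], signs[sel]):
                i = np.searchsorted(summits, a - halfwidth, side="left")
                j = np.searchsorted(summits, a + halfwidth, side="right")
                if j > i:
                    offsets_all.append((summits[i:j] - a) * sg)
        offs = (np.concatenate(offsets_all) if offsets_all
                else np.empty(0, dtype=float))
        counts, _ = np.histogram(offs[(offs >= -halfwidth) & (offs < halfwidth)],
                                 bins=edges)
        profiles[factor] = CompositeProfile(
            factor=factor, bin_edges=edges,
            values=counts / max(len(genes), 1), n_anchors=len(genes))
    return profiles


# ---------------------------------------------------------------------------
# architecture call
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ArchitectureCall:
    """Shared-occupancy window and per-factor flanks, in signed bp.

    Windows are half-open ``[left, right)`` intervals on the profile's
    offset axis; ``overlap_window`` is ``None`` when no bin is active for
    all factors simultaneously (width 0).
    """

    overlap_window: tuple[float, float] | None
    specific_windows: dict[str, list[tuple[float, float]]]
    offset_estimate: dict[str, float]
    threshold_used: float

    @property
    def overlap_width(self) -> float:
        if self.overlap_window is None:
            return 0.0
        return self.overlap_window[1] - self.overlap_window[0]

    def specific_width(self, factor: str) -> float:
        return sum(r - l for l, r in self.specific_windows.get(factor, []))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open index intervals."""
    runs, start = [], None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


def detect_architecture(profiles: Mapping[str, CompositeProfile],
                        occupancy_threshold_frac: float = 0.5,
                        ) -> ArchitectureCall:
    """Call the composite binding architecture from aligned profiles.

    A bin is *active* for a factor when its profile value reaches
    ``occupancy_threshold_frac`` times that factor's own maximum (a
    scale-free, per-factor threshold).  The overlap window is the longest
    contiguous run of bins active for every factor; each factor's specific
    windows are the maximal runs active for exactly that factor.  Offset
    estimates are occupancy-weighted mean offsets over active bins.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    factors = list(profiles)
    edges = profiles[factors[0]].bin_edges
    for f in factors[1:]:
        if not np.array_equal(profiles[f].bin_edges, edges):
            raise ValueError("profiles must share identical bins")
    centers = (edges[:-1] + edges[1:]) / 2.0

    active, offset_estimate = {}, {}
    for f in factors:
        v = profiles[f].values
        vmax = v.max()
        if vmax <= 0:
            raise ValueError(f"flat profile for factor {f!r}")
        act = v >= occupancy_threshold_frac * vmax
        active[f] = act
        offset_estimate[f] = float(np.average(centers[act], weights=v[act]))

    stack = np.vstack([active[f] for f in factors])
    all_active = stack.all(axis=0)
    n_active = stack.sum(axis=0)

    overlap = None
    runs = _runs(all_active)
    if runs:
        i, j = max(runs, key=lambda r: (r[1] - r[0], -r[0]))
        overlap = (float(edges[i]), float(edges[j]))

    specific = {}
    for fi, f in enumerate(factors):
        only = active[f] & (n_active == 1)
        specific[f] = [(float(edges[i]), float(edges[j]))
                       for i, j in _runs(only)]
    return ArchitectureCall(overlap_window=overlap, specific_windows=specific,
                            offset_estimate=offset_estimate,
                            threshold_used=occupancy_threshold_frac)


def genes_with_architecture(pairs: pd.DataFrame, call: ArchitectureCall,
                            anchors: pd.Series, annotation: pd.DataFrame,
                            factor_a: str, factor_b: str) -> set[str]:
    """Genes whose own summit offsets are consistent with the called windows.

    For each co-bound gene, the representative summit of each factor
    (``summit_a``/``summit_b`` of ``pairs``) is converted to a
    transcription-direction offset from the gene's anchor; the gene is kept
    when every factor's offset lies inside the overlap window or one of
    that factor's specific windows (half-open interval tests, matching the
    profile bins).
    """
    meta = annotation.set_index("gene_id")

    def allowed(factor: str) -> list[tuple[float, float]]:
        wins = list(call.specific_windows.get(factor, []))
        if call.overlap_window is not None:
            wins.append(call.overlap_window)
        return wins

    wins = {factor_a: allowed(factor_a), factor_b: allowed(factor_b)}
    keep = set()
    for row in pairs.itertuples(index=False):
        if row.gene_id not in anchors.index:
            continue
        a = anchors.loc[row.gene_id]
        sg = -1 if meta.loc[row.gene_id, "strand"] == "-" else 1
        ok = True
        for factor, summit in ((factor_a, row.summit_a), (factor_b, row.summit_b)):
            off = (summit - a) * sg
            if not any(l <= off < r for l, r in wins[factor]):
                ok = False
                break
        if ok:
            keep.add(row.gene_id)
    return keep
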