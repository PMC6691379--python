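"""Gene-signature derivation and expression summaries.

Signatures are built by set algebra over named gene sets (the bound /
co-bound / architecture-consistent sets produced upstream), with the
provenance expression recorded alongside the sorted gene list.  Expression
summaries cover median log2 fold changes against a reference group,
top-N selection by fold change, and Ward hierarchical clustering.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# set algebra
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GeneSignature:
    name: str
    genes: list[str]       # sorted, no duplicates
    provenance: str        # the set-algebra expression that produced it

    def __len__(self) -> int:
        return len(self.genes)


_OPS = {"∩": "and", "&": "and", "∪": "or", "|": "or", "\\": "diff", "-": "diff"}


def _tokenize(expression: str) -> list[str]:
    tokens, buf = [], []
    for ch in expression:
        if ch.isspace() or ch in _OPS or ch in "()":
            if buf:
                tokens.append("".join(buf))
                buf = []
            if ch in _OPS or ch in "()":
                tokens.append(ch)
        else:
            buf.append(ch)
    if buf:
        tokens.append("".join(buf))
    return tokens


def _evaluate(tokens: list[str], pos: int,
              sets: Mapping[str, set[str]]) -> tuple[set[str], int]:
    def term(p: int) -> tuple[set[str], int]:
        if p >= len(tokens):
            raise ValueError("unexpected end of expression")
        t = tokens[p]
        if t == "(":
            value, p = _evaluate(tokens, p + 1, sets)
            if p >= len(tokens) or tokens[p] != ")":
                raise ValueError("unbalanced parentheses")
            return value, p + 1
        if t in _OPS or t == ")":
            raise ValueError(f"expected set name, got {t!r}")
        if t not in sets:
            raise ValueError(f"unknown set name {t!r}")
        return set(sets[t]), p + 1

    value, pos = term(pos)
    while pos < len(tokens) and tokens[pos] in _OPS:
        op = _OPS[tokens[pos]]
        rhs, pos = term(pos + 1)
        if op == "and":
            value &= rhs
        elif op == "or":
            value |= rhs
        else:
            value -= rhs
    return value, pos


def derive_signature(sets: Mapping[str, set[str] | Sequence[str]],
                     expression: str, name: str = "signature") -> GeneSignature:
    """Evaluate a set-algebra expression over named gene sets.

    Operators ``∩``/``&``, ``∪``/``|`` and ``\\``/``-`` associate left to
    right with equal precedence; parentheses group.  The result is sorted
    lexicographically and carries the expression as provenance.
    """
    sets = {k: set(v) for k, v in sets.items()}
    tokens = _tokenize(expression)
    value, pos = _evaluate(tokens, 0, sets)
    if pos != len(tokens):
        raise ValueError(f"trailing tokens in expression: {tokens[pos:]}")
    return GeneSignature(name=name, genes=sorted(value), provenance=expression)


# ---------------------------------------------------------------------------
# fold-change summaries
# ---------------------------------------------------------------------------

def median_foldchange(matrix: pd.DataFrame, genes: Sequence[str],
                      labels: pd.Series, reference: str) -> pd.DataFrame:
    """Median log2 fold change per gene per group against a reference.

    The matrix is assumed to be on a log2 scale already, so the fold
    change of a sample is its value minus the gene's median over reference
    samples; per group the median over samples is reported.  The reference
    group's own column is identically 0 by construction.
    """
    missing = [g for g in genes if g not in matrix.index]
    if missing:
        logger.warning("median_foldchange: %d gene(s) absent from matrix",
                       len(missing))
    present = [g for g in genes if g in matrix.index]
    sub = matrix.loc[present]
    lab = labels.loc[list(matrix.columns)]
    ref_med = sub.loc[:, lab == reference].median(axis=1)
    centered = sub.sub(ref_med, axis=0)
    out = {}
    for group in pd.unique(lab):
        out[group] = centered.loc[:, lab == group].median(axis=1)
    return pd.DataFrame(out)


def top_n_by_foldchange(fold_changes: pd.Series, n: int,
                        direction: str = "down") -> list[str]:
    """Top-n genes by fold change; ties break lexicographically by gene id.

    ``direction="down"`` selects the most negative fold changes (the
    usual "top down-regulated genes" pick), ``"up"`` the most positive.
    """
    if direction not in ("down", "up"):
        raise ValueError("direction must be 'down' or 'up'")
    if n > len(fold_changes):
        logger.info("top_n_by_foldchange: n=%d > %d genes; returning all",
                    n, len(fold_changes))
    ascending = direction == "down"
    ordered = fold_changes.sort_index().sort_values(
        ascending=ascending, kind="mergesort")
    return list(ordered.index[:n])


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

def ward_cluster(matrix: pd.DataFrame, k: int | None = None,
                 height: float | None = None,
                 ) -> tuple[pd.Series, np.ndarray]:
    """Agglomerative clustering of the rows: Euclidean distance, Ward.D2.

    Ward's variance criterion is applied to unsquared Euclidean distances
    (the "Ward.D2" semantics), with deterministic merge order (lowest
    original index breaks exact ties).  Exactly one of ``k`` (number of
    flat clusters) or ``height`` (tree cut distance) must be given.

    Returns ``(labels, merge_tree)`` where ``merge_tree`` is the scipy
    linkage matrix.
    """
    if (k is None) == (height is None):
        raise ValueError("give exactly one of k or height")
    Z = linkage(matrix.to_numpy(dtype=float), method="ward",
                metric="euclidean")
    if k is not None:
        flat = fcluster(Z, t=k, criterion="maxclust")
    else:
        flat = fcluster(Z, t=height, criterion="distance")
    return pd.Series(flat, index=matrix.index, name="cluster"), Z
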