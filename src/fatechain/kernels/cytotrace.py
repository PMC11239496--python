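"""Developmental-potential scoring from expressed-gene counts.

The score rests on the observation that the number of genes a cell
expresses decays with maturity (less-developed cells regulate chromatin
less tightly).  Construction: (1) count expressed genes per cell (GEC);
(2) correlate every gene with GEC; (3) average the neighbor-smoothed
expression of the top-L correlated genes; (4) min–max scale to [0, 1].
High score = naive; the pseudotime is the inverted score p = 1 − c.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from ..datatypes import NeighborGraph
from ..markov import knn_smooth
from .pseudotime import PseudotimeVector

__all__ = [
    "CytoTraceScore",
    "gene_expressed_count",
    "cytotrace_score",
    "cytotrace_pseudotime",
]


@dataclass
class CytoTraceScore:
    gec: np.ndarray  # per-cell expressed-gene count
    score: np.ndarray  # c, min-max scaled to [0, 1]
    top_genes: np.ndarray  # indices of the L genes used
    L: int


def gene_expressed_count(X: np.ndarray | sp.spmatrix) -> np.ndarray:
    """GEC_j = number of genes with strictly positive expression in cell j."""
    if sp.issparse(X):
        return np.asarray((X > 0).sum(axis=1)).ravel().astype(int)
    X = np.asarray(X)
    if not np.all(np.isfinite(X)):
        raise ValueError("expression matrix contains non-finite values")
    return (X > 0).sum(axis=1).astype(int)


def _pearson_with_vector(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Columnwise Pearson correlation of X with y; zero-variance → 0."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    num = Xc.T @ yc
    den = np.sqrt((Xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return r


def cytotrace_score(
    X: np.ndarray | sp.spmatrix, graph: NeighborGraph, L: int = 200
) -> CytoTraceScore:
    """Compute the developmental-potential score c ∈ [0, 1] per cell.

    Correlations with GEC are taken on the unsmoothed matrix; smoothing
    enters only when aggregating the top-L genes.  Zero-variance genes get
    correlation 0; ties at the L-th rank break by gene index so builds are
    deterministic.
    """
    Xd = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, dtype=float)
    n_g = Xd.shape[1]
    if not 1 <= L <= n_g:
        raise ValueError(f"L must lie in [1, {n_g}], got {L}")
    gec = gene_expressed_count(Xd)
    if gec.min() == gec.max():
        raise ValueError("expressed-gene count is constant; correlations undefined")
    r = _pearson_with_vector(Xd, gec.astype(float))
    # sort by (-correlation, gene index): deterministic under ties
    order = np.lexsort((np.arange(n_g), -r))
    top = np.sort(order[:L])
    smoothed = knn_smooth(Xd, graph)
    c_tilde = smoothed[:, top].mean(axis=1)
    span = c_tilde.max() - c_tilde.min()
    if span <= 0:
        raise ValueError("aggregated score is constant; cannot scale to [0, 1]")
    c = (c_tilde - c_tilde.min()) / span
    return CytoTraceScore(gec=gec, score=c, top_genes=top, L=L)


def cytotrace_pseudotime(score: CytoTraceScore) -> PseudotimeVector:
    """p = 1 − c: naive cells (c near 1) get small pseudotime."""
    return PseudotimeVector(values=1.0 - score.score, source="cytotrace")
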