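"""Pseudotime-directed transition kernel.

Given a similarity graph with adjacency C̃ and a per-cell pseudotime t,
edges are reweighted C_jk = C̃_jk · f(Δt_jk) with Δt_jk = t_k − t_j, so
transitions toward the pseudotemporal future are favored.  Two thresholding
schemes are provided:

soft
    f(Δt) = 1 for Δt ≥ 0 and f(Δt) = 2 / (1 + exp(−b·Δt))^(1/ν) for Δt < 0.
    Edges into the past are continuously downweighted: f is strictly
    increasing on Δt < 0, tends to 0 in the deep past, and jumps from a
    left limit of 2^(1−1/ν) to 1 at Δt = 0.  The commonly printed variant
    with exp(+b·Δt) *grows* toward the past and would invert the intended
    bias; the sign used here is the one consistent with downweighting
    backward edges.  Defaults b = 10, ν = 0.5.

hard
    Edges with Δt ≥ 0 are kept; among each cell's past-pointing edges only
    the fraction with smallest |Δt| survives.  Every cell keeps at least
    one outgoing edge (its least-backward one) so no row empties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from ..datatypes import NeighborGraph, TransitionMatrix
from ..markov import row_normalize

__all__ = [
    "PseudotimeVector",
    "SoftSchemeParams",
    "soft_weight",
    "hard_weights",
    "pseudotime_transition_matrix",
]


@dataclass
class SoftSchemeParams:
    """Soft thresholding parameters: steepness b and shape ν."""

    b: float = 10.0
    nu: float = 0.5

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError(f"b must be > 0, got {self.b}")
        if self.nu <= 0:
            raise ValueError(f"nu must be > 0, got {self.nu}")


@dataclass
class PseudotimeVector:
    """Per-cell scalar ordering.  ``source`` records where it came from."""

    values: np.ndarray
    source: str = "user"  # user | cytotrace | realtime_informed

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("pseudotime must be a 1-D vector")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("pseudotime contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)


def soft_weight(delta_t, params: SoftSchemeParams | None = None):
    """Soft-scheme edge multiplier f(Δt); vectorized over ``delta_t``."""
    if params is None:
        params = SoftSchemeParams()
    dt = np.asarray(delta_t, dtype=float)
    if not np.all(np.isfinite(dt)):
        raise ValueError("pseudotime differences must be finite")
    out = np.ones_like(dt)
    past = dt < 0
    # 2 / (1 + e^{-b·Δt})^{1/ν}: → 0 as Δt → −∞, left limit 2^{1−1/ν} at 0⁻
    out[past] = 2.0 / (1.0 + np.exp(-params.b * dt[past])) ** (1.0 / params.nu)
    if np.isscalar(delta_t) or np.ndim(delta_t) == 0:
        return float(out)
    return out


def hard_weights(
    graph: NeighborGraph, pt: PseudotimeVector, frac_retain: float = 0.2
) -> sp.csr_matrix:
    """0/1 edge multipliers implementing the hard thresholding policy."""
    if not 0.0 <= frac_retain <= 1.0:
        raise ValueError(f"frac_retain must lie in [0, 1], got {frac_retain}")
    A = graph.adjacency
    t = pt.values
    keep = sp.lil_matrix(A.shape)
    for j in range(graph.n_cells):
        nbrs = graph.neighborhood(j)
        dt = t[nbrs] - t[j]
        future = nbrs[dt >= 0]
        past = nbrs[dt < 0]
        kept = list(future)
        if past.size:
            order = np.argsort(np.abs(t[past] - t[j]), kind="stable")
            n_keep = int(np.floor(frac_retain * past.size))
            kept.extend(past[order[:n_keep]])
            if not kept:  # fallback: at least one outgoing edge
                kept.append(past[order[0]])
        keep[j, kept] = 1.0
    return sp.csr_matrix(keep)


def pseudotime_transition_matrix(
    graph: NeighborGraph,
    pt: PseudotimeVector,
    scheme: str = "soft",
    params: SoftSchemeParams | None = None,
    frac_retain: float = 0.2,
) -> TransitionMatrix:
    """Bias graph edges toward increasing pseudotime and row-normalize."""
    if len(pt) != graph.n_cells:
        raise ValueError("pseudotime and graph cover different numbers of cells")
    A = sp.csr_matrix(graph.adjacency, copy=True)
    t = pt.values
    if scheme == "soft":
        rows = np.repeat(np.arange(graph.n_cells), np.diff(A.indptr))
        dt = t[A.indices] - t[rows]
        A.data = A.data * soft_weight(dt, params)
    elif scheme == "hard":
        A = A.multiply(hard_weights(graph, pt, frac_retain)).tocsr()
    else:
        raise ValueError(f"unknown scheme {scheme!r}; use 'soft' or 'hard'")
    sums = np.asarray(A.sum(axis=1)).ravel()
    empty = np.flatnonzero(sums <= 0)
    if empty.size:
        raise ValueError(
            f"rows reweighted to zero for cells {empty.tolist()}; "
            "consider the soft scheme, which never zeroes an edge"
        )
    return row_normalize(A)
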