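"""Velocity-field transition kernel.

Any high-dimensional per-cell velocity matrix V (RNA velocity, or rates
derived from metabolic labeling via α − γ·r) is turned into transition
probabilities: for each cell j, the cosine similarity between V_j and the
displacement x_k − x_j toward each neighbor k is passed through a softmax
over the neighborhood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from ..datatypes import NeighborGraph, TransitionMatrix

__all__ = ["VelocityField", "velocity_transition_matrix"]


@dataclass
class VelocityField:
    """n_c×n_g expression-space velocities; NaN marks missing entries."""

    V: np.ndarray
    gene_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        if self.V.ndim != 2:
            raise ValueError("velocity matrix must be 2-D")
        if np.any(np.isinf(self.V)):
            raise ValueError("velocity matrix contains infinities")


def velocity_transition_matrix(
    graph: NeighborGraph,
    X: np.ndarray,
    V: VelocityField | np.ndarray,
    softmax_scale: float = 4.0,
) -> TransitionMatrix:
    """Cosine-similarity softmax kernel over graph neighborhoods.

    Cells with zero-norm (or all-missing) velocity fall back to a uniform
    row over their neighbors; a warning reports how many.
    """
    Vm = V.V if isinstance(V, VelocityField) else np.asarray(V, dtype=float)
    X = np.asarray(X, dtype=float)
    if Vm.shape != X.shape:
        raise ValueError(f"velocity shape {Vm.shape} != expression shape {X.shape}")
    if X.shape[0] != graph.n_cells:
        raise ValueError("graph and expression cover different numbers of cells")

    n = graph.n_cells
    rows, cols, vals = [], [], []
    n_uniform = 0
    for j in range(n):
        nbrs = graph.neighborhood(j)
        v = Vm[j]
        usable = np.isfinite(v)
        disp = X[nbrs] - X[j]
        vn = np.linalg.norm(v[usable]) if usable.any() else 0.0
        if vn == 0.0:
            probs = np.full(len(nbrs), 1.0 / len(nbrs))
            n_uniform += 1
        else:
            d = disp[:, usable]
            dn = np.linalg.norm(d, axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                cos = np.where(dn > 0, (d @ v[usable]) / (dn * vn), 0.0)
            logits = softmax_scale * cos
            logits -= logits.max()
            e = np.exp(logits)
            probs = e / e.sum()
        rows.extend([j] * len(nbrs))
        cols.extend(nbrs)
        vals.extend(probs)
    if n_uniform:
        warnings.warn(
            f"{n_uniform} cells with zero-norm velocity fell back to uniform rows",
            stacklevel=2,
        )
    P = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return TransitionMatrix(P)
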