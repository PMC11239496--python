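"""Markov-chain plumbing shared by all kernels and the estimator.

Row normalization, neighbor smoothing, convex kernel combination, the
backward (transposed) chain used for initial-state identification,
embedding projection of a transition matrix, and random-walk sampling.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .datatypes import NeighborGraph, RandomWalk, TransitionMatrix

__all__ = [
    "row_normalize",
    "knn_smooth",
    "combine_kernels",
    "backward_chain",
    "project_transitions",
    "sample_random_walks",
]


def row_normalize(M: sp.spmatrix | np.ndarray, direction: str = "forward") -> TransitionMatrix:
    """Divide each row of a non-negative matrix by its sum.

    Raises
    ------
    ValueError
        If a row is all zero (the offending cell indices are named).
    """
    M = sp.csr_matrix(M, dtype=float)
    if M.nnz and M.data.min() < 0:
        raise ValueError("matrix has negative entries")
    sums = np.asarray(M.sum(axis=1)).ravel()
    empty = np.flatnonzero(sums <= 0)
    if empty.size:
        raise ValueError(f"cannot row-normalize: all-zero rows for cells {empty.tolist()}")
    P = sp.diags(1.0 / sums) @ M
    return TransitionMatrix(P, direction=direction)


def knn_smooth(X: np.ndarray | sp.spmatrix, graph: NeighborGraph) -> np.ndarray:
    """First-order-moment smoothing: X̃_j = mean of X over N(j) ∪ {j}.

    Unweighted, the cell itself included — so constants are preserved and
    the operation is idempotent on constant columns.
    """
    if X.shape[0] != graph.n_cells:
        raise ValueError(
            f"X has {X.shape[0]} rows but graph covers {graph.n_cells} cells"
        )
    A = graph.adjacency.copy()
    A.data[:] = 1.0  # unweighted mean over the neighborhood
    A = A + sp.eye(graph.n_cells, format="csr")
    counts = np.asarray(A.sum(axis=1)).ravel()
    S = sp.diags(1.0 / counts) @ A
    out = S @ X
    if sp.issparse(out):
        out = np.asarray(out.todense())
    return np.asarray(out)


def combine_kernels(
    T1: TransitionMatrix, T2: TransitionMatrix, alpha: float
) -> TransitionMatrix:
    """Convex combination T = α·T1 + (1−α)·T2 of two transition matrices."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    if T1.shape != T2.shape:
        raise ValueError(f"shape mismatch: {T1.shape} vs {T2.shape}")
    if T1.direction != T2.direction:
        raise ValueError("cannot combine forward with backward chains")
    if alpha == 1.0:
        return T1
    if alpha == 0.0:
        return T2
    P = alpha * T1.P + (1.0 - alpha) * T2.P
    return TransitionMatrix(P, direction=T1.direction)


def backward_chain(T: TransitionMatrix) -> TransitionMatrix:
    """Transpose and row-normalize: probabilities toward putative ancestors.

    A cell that is unreachable under the forward chain produces an all-zero
    transposed row; such cells are reported in the error.
    """
    if T.direction != "forward":
        raise ValueError("backward_chain expects a forward chain")
    Pt = sp.csr_matrix(T.P.T)
    sums = np.asarray(Pt.sum(axis=1)).ravel()
    empty = np.flatnonzero(sums <= 0)
    if empty.size:
        raise ValueError(
            f"cells unreachable under the forward chain: {empty.tolist()}"
        )
    return row_normalize(Pt, direction="backward")


def project_transitions(
    T: TransitionMatrix, graph: NeighborGraph, Z: np.ndarray
) -> np.ndarray:
    """Project a graph-based chain into a low-dimensional embedding.

    v_j = Σ_{n∈N(j)} (T_jn − 1/k_j)(z_n − z_j): the displacement expected
    under the chain minus the uniform-neighbor baseline, so a kernel that
    is indifferent among neighbors projects to the zero vector.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.shape[0] != T.n_cells:
        raise ValueError("embedding rows must match the number of cells")
    if graph.n_cells != T.n_cells:
        raise ValueError("graph and transition matrix cover different cells")
    P = T.P
    V = np.zeros((T.n_cells, Z.shape[1]))
    deg = graph.degree
    for j in range(T.n_cells):
        nbrs = graph.neighborhood(j)
        row = P.indices[P.indptr[j]: P.indptr[j + 1]]
        probs = P.data[P.indptr[j]: P.indptr[j + 1]]
        outside = np.setdiff1d(row, np.append(nbrs, j), assume_unique=False)
        if outside.size:
            raise ValueError(
                f"transition mass of cell {j} outside its neighborhood "
                f"(cells {outside.tolist()}): kernel is not graph-based"
            )
        t_full = np.zeros(len(nbrs))
        pos = {k: i for i, k in enumerate(nbrs)}
        for k, p in zip(row, probs):
            if k in pos:  # self-mass contributes zero displacement anyway
                t_full[pos[k]] = p
        disp = Z[nbrs] - Z[j]
        V[j] = (t_full - 1.0 / deg[j]) @ disp
    return V


def sample_random_walks(
    T: TransitionMatrix,
    starts: np.ndarray | list[int],
    n_walks: int,
    max_steps: int,
    stop_set: set[int] | None = None,
    seed: int = 0,
) -> list[RandomWalk]:
    """Sample categorical random walks under the chain.

    Starts are drawn uniformly (with replacement) from ``starts``; each walk
    stops upon entering ``stop_set`` or after ``max_steps`` transitions.
    Identical seeds yield identical walks.
    """
    starts = np.asarray(starts, dtype=int)
    if starts.size == 0:
        raise ValueError("starts must be non-empty")
    if max_steps < 1:
        raise ValueError("max_steps must be ≥ 1")
    if starts.min() < 0 or starts.max() >= T.n_cells:
        raise ValueError("start index out of range")
    stop = frozenset(stop_set) if stop_set is not None else frozenset()
    rng = np.random.default_rng(seed)
    P = T.P
    walks: list[RandomWalk] = []
    for _ in range(n_walks):
        state = int(rng.choice(starts))
        path = [state]
        reason = "max_steps"
        for _ in range(max_steps):
            if state in stop:
                reason = "terminal_set"
                break
            lo, hi = P.indptr[state], P.indptr[state + 1]
            nxt = P.indices[lo:hi]
            probs = P.data[lo:hi]
            state = int(rng.choice(nxt, p=probs / probs.sum()))
            path.append(state)
        else:
            if state in stop:
                reason = "terminal_set"
        walks.append(RandomWalk(states=np.asarray(path), stop_reason=reason, seed=seed))
    return walks
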