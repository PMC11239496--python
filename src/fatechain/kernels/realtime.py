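"""Time-course kernel: one global Markov chain over all time points.

Inter-time-point couplings (optimal transport between consecutive
snapshots) sit on the first off-diagonal of a block matrix; intra-time-
point similarity transitions sit on the diagonal.  The two are mixed
convexly per row (``conn_weight`` on the similarity part), the chain is
row-normalized, optionally sparsified by an adaptive threshold, and can be
turned into a real-time-informed pseudotime via diffusion components of
the symmetrized chain.

A balanced entropic (Sinkhorn) solver is included as plumbing for desk-
scale problems; externally computed couplings (e.g. from Waddington-OT)
always take precedence when supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import cdist

from ..datatypes import NeighborGraph, TransitionMatrix
from ..markov import row_normalize
from .pseudotime import PseudotimeVector

__all__ = [
    "TransportMap",
    "GlobalChain",
    "sinkhorn_coupling",
    "assemble_global_chain",
    "adaptive_threshold",
    "realtime_informed_pseudotime",
]


@dataclass
class TransportMap:
    """Non-negative coupling between cells at two consecutive time points."""

    coupling: np.ndarray
    source_time: float
    target_time: float

    def __post_init__(self) -> None:
        self.coupling = np.asarray(self.coupling, dtype=float)
        if self.coupling.min() < 0:
            raise ValueError("coupling must be non-negative")
        if np.any(self.coupling.sum(axis=1) <= 0):
            raise ValueError("coupling has all-zero rows")


@dataclass
class GlobalChain:
    """Row-stochastic chain over all cells of all time points.

    Nonzeros of a row at time t lie only in t's own block and the next
    block (final time point: own block only).
    """

    T: TransitionMatrix
    time_labels: np.ndarray
    conn_weight: float
    threshold: float | None = None

    @property
    def n_cells(self) -> int:
        return self.T.n_cells

    def blocks(self) -> list[np.ndarray]:
        """Cell index arrays per time point, in increasing time order."""
        times = np.unique(self.time_labels)
        return [np.flatnonzero(self.time_labels == t) for t in times]


def per_timepoint_graph(
    coords: np.ndarray, time: np.ndarray, n_neighbors: int = 15, mode: str = "distance"
) -> NeighborGraph:
    """Similarity graph with kNN edges restricted to each time block.

    Intra-time-point transitions should reflect similarity among
    contemporaneous cells; a global kNN graph can orphan cells whose
    neighbors all sit in other snapshots.
    """
    coords = np.asarray(coords, dtype=float)
    time = np.asarray(time)
    n = len(time)
    A = sp.lil_matrix((n, n))
    for t in np.unique(time):
        idx = np.flatnonzero(time == t)
        sub = NeighborGraph.from_embedding(
            coords[idx], n_neighbors=min(n_neighbors, len(idx) - 1), mode=mode
        )
        A[np.ix_(idx, idx)] = sub.adjacency.todense()
    return NeighborGraph(sp.csr_matrix(A))


def sinkhorn_coupling(
    X_src: np.ndarray,
    X_tgt: np.ndarray,
    epsilon: float | None = None,
    max_iter: int = 10_000,
    tol: float = 1e-6,
) -> TransportMap:
    """Balanced entropic OT between uniform marginals, squared-Euclidean cost.

    ``epsilon`` defaults to 0.05 × median pairwise cost.  Raises if the
    marginal violation has not dropped below ``tol`` within ``max_iter``
    Sinkhorn iterations.
    """
    X_src = np.atleast_2d(np.asarray(X_src, dtype=float))
    X_tgt = np.atleast_2d(np.asarray(X_tgt, dtype=float))
    if X_src.shape[0] == 0 or X_tgt.shape[0] == 0:
        raise ValueError("source and target sets must be non-empty")
    C = cdist(X_src, X_tgt, metric="sqeuclidean")
    if epsilon is None:
        med = np.median(C)
        epsilon = 0.05 * med if med > 0 else 1.0
    if epsilon <= 0:
        raise ValueError(f"epsilon must be > 0, got {epsilon}")
    n, m = C.shape
    a = np.full(n, 1.0 / n)
    b = np.full(m, 1.0 / m)
    # log-domain iterations: stable for small epsilon
    f = np.zeros(n)
    g = np.zeros(m)
    err = np.inf
    for _ in range(max_iter):
        f = -epsilon * _logsumexp_rows((g[None, :] - C) / epsilon) + epsilon * np.log(a)
        g = -epsilon * _logsumexp_rows((f[:, None] - C).T / epsilon) + epsilon * np.log(b)
        P = np.exp((f[:, None] + g[None, :] - C) / epsilon)
        err = max(
            np.abs(P.sum(axis=1) - a).max(), np.abs(P.sum(axis=0) - b).max()
        )
        if err < tol:
            break
    else:
        raise RuntimeError(
            f"Sinkhorn did not converge in {max_iter} iterations "
            f"(marginal error {err:.2e})"
        )
    return TransportMap(coupling=P, source_time=0.0, target_time=1.0)


def _logsumexp_rows(A: np.ndarray) -> np.ndarray:
    mx = A.max(axis=1, keepdims=True)
    return (mx + np.log(np.exp(A - mx).sum(axis=1, keepdims=True))).ravel()


def assemble_global_chain(
    couplings: list[TransportMap],
    graph: NeighborGraph,
    time: np.ndarray,
    conn_weight: float = 0.2,
    self_transitions: str = "all",
) -> GlobalChain:
    """Place couplings on the first off-diagonal, similarity on the diagonal.

    With ``self_transitions='all'``, a row at a non-final time point is
    conn_weight·(row-normalized intra-block similarity) +
    (1−conn_weight)·(row-normalized coupling row); final-time rows use the
    intra-block similarity alone.  ``'last'`` keeps the diagonal only at
    the final time point; ``'none'`` additionally gives final-time cells
    pure self-loops.
    """
    if not 0.0 <= conn_weight <= 1.0:
        raise ValueError(f"conn_weight must lie in [0, 1], got {conn_weight}")
    if self_transitions not in ("all", "last", "none"):
        raise ValueError(f"unknown self_transitions {self_transitions!r}")
    time = np.asarray(time)
    if len(time) != graph.n_cells:
        raise ValueError("time labels and graph cover different numbers of cells")
    times = np.unique(time)
    blocks = [np.flatnonzero(time == t) for t in times]
    cmap = {}
    for cp in couplings:
        cmap[(cp.source_time, cp.target_time)] = cp
    n = graph.n_cells
    T = sp.lil_matrix((n, n))
    A = graph.adjacency
    for bi, idx in enumerate(blocks):
        final = bi == len(blocks) - 1
        intra = sp.csr_matrix(A[np.ix_(idx, idx)])
        intra_sums = np.asarray(intra.sum(axis=1)).ravel()
        if not final:
            key = (times[bi], times[bi + 1])
            if key not in cmap:
                raise ValueError(
                    f"missing coupling for consecutive time points {key}"
                )
            cp = cmap[key].coupling
            nxt = blocks[bi + 1]
            if cp.shape != (len(idx), len(nxt)):
                raise ValueError(
                    f"coupling for {key} has shape {cp.shape}, "
                    f"expected {(len(idx), len(nxt))}"
                )
            cp_norm = cp / cp.sum(axis=1, keepdims=True)
            use_intra = self_transitions == "all"
            for r, j in enumerate(idx):
                if use_intra and intra_sums[r] > 0:
                    row_intra = intra[r].toarray().ravel() / intra_sums[r]
                    T[j, idx] = conn_weight * row_intra
                    T[j, nxt] = (1.0 - conn_weight) * cp_norm[r]
                else:
                    T[j, nxt] = cp_norm[r]
        else:
            if self_transitions == "none":
                for j in idx:
                    T[j, j] = 1.0
            else:
                empty = idx[intra_sums <= 0]
                if empty.size:
                    raise ValueError(
                        "final-time cells without intra-block neighbors: "
                        f"{empty.tolist()}"
                    )
                norm = sp.diags(1.0 / intra_sums) @ intra
                T[np.ix_(idx, idx)] = norm.todense()
    chain = GlobalChain(
        T=row_normalize(sp.csr_matrix(T)),
        time_labels=time,
        conn_weight=conn_weight,
    )
    _check_block_support(chain)
    return chain


def _check_block_support(chain: GlobalChain) -> None:
    blocks = chain.blocks()
    allowed = {}
    for bi, idx in enumerate(blocks):
        ok = set(idx.tolist())
        if bi + 1 < len(blocks):
            ok |= set(blocks[bi + 1].tolist())
        for j in idx:
            allowed[j] = ok
    P = chain.T.P
    for j in range(chain.n_cells):
        cols = P.indices[P.indptr[j]: P.indptr[j + 1]]
        bad = [c for c in cols if c not in allowed[j]]
        if bad:
            raise AssertionError(
                f"row {j} has transition mass outside its own/next time block: {bad}"
            )


def adaptive_threshold(chain: GlobalChain, tau="auto", target: str = "couplings") -> GlobalChain:
    """Sparsify the global chain without emptying any row.

    ``tau='auto'`` uses the largest threshold guaranteed to leave every
    (targeted part of a) row non-empty, τ = min_j max_k T_jk: entries
    strictly below τ are zeroed, survivors kept unchanged, then rows are
    renormalized.  ``'auto_per_time'`` applies the rule within each time
    block's rows independently.  A numeric τ is applied as given and
    rejected if it would empty a row.

    ``target='couplings'`` (default) restricts the rule to the
    inter-time-point entries — entropic regularization makes the transport
    maps dense, whereas the intra-time similarity blocks are kNN-sparse
    already; ``target='chain'`` applies it to entire rows.  Re-applying
    the auto rule to an already-thresholded chain is a no-op (the recorded
    threshold is kept), so auto thresholding is idempotent.
    """
    if target not in ("couplings", "chain"):
        raise ValueError(f"unknown target {target!r}")
    if chain.threshold is not None and tau in ("auto", "auto_per_time"):
        return chain
    P = chain.T.P.tocsr(copy=True)
    mask = None  # boolean per nnz entry: eligible for thresholding
    if target == "couplings":
        blocks = chain.blocks()
        next_block = {}
        for bi, idx in enumerate(blocks):
            nxt = set(blocks[bi + 1].tolist()) if bi + 1 < len(blocks) else set()
            for j in idx:
                next_block[j] = nxt
        mask = np.zeros(P.nnz, dtype=bool)
        for j in range(P.shape[0]):
            lo, hi = P.indptr[j], P.indptr[j + 1]
            nxt = next_block[j]
            mask[lo:hi] = [c in nxt for c in P.indices[lo:hi]]
    else:
        mask = np.ones(P.nnz, dtype=bool)

    def _row_max_eligible(rows: np.ndarray) -> float:
        """min over rows (with eligible entries) of the eligible max."""
        t_val = np.inf
        for j in rows:
            lo, hi = P.indptr[j], P.indptr[j + 1]
            el = P.data[lo:hi][mask[lo:hi]]
            if el.size:
                t_val = min(t_val, el.max())
        return t_val

    if tau == "auto":
        t = _row_max_eligible(np.arange(P.shape[0]))
        P.data[mask & (P.data < t)] = 0.0
    elif tau == "auto_per_time":
        t = np.inf
        for idx in chain.blocks():
            t_block = _row_max_eligible(idx)
            if not np.isfinite(t_block):
                continue
            t = min(t, t_block)
            for j in idx:
                lo, hi = P.indptr[j], P.indptr[j + 1]
                sel = mask[lo:hi] & (P.data[lo:hi] < t_block)
                P.data[lo:hi][sel] = 0.0
    else:
        t = float(tau)
        P.data[mask & (P.data < t)] = 0.0
        sums = np.asarray(P.sum(axis=1)).ravel()
        empty = np.flatnonzero(sums <= 0)
        if empty.size:
            raise ValueError(
                f"threshold {t} empties rows for cells {empty.tolist()}"
            )
    P.eliminate_zeros()
    return GlobalChain(
        T=row_normalize(P),
        time_labels=chain.time_labels,
        conn_weight=chain.conn_weight,
        threshold=float(t),
    )


def realtime_informed_pseudotime(
    chain: GlobalChain, root: int, n_components: int = 15
) -> PseudotimeVector:
    """Diffusion-pseudotime on the symmetrized global chain.

    S = rownorm(T + Tᵀ); the top ``n_components`` eigenpairs (λ_i, ψ_i) of
    S excluding the stationary one define diffusion components
    M_j = (λ_i/(1−λ_i))·ψ_i(j); the pseudotime of cell j is the Euclidean
    distance ‖M_j − M_root‖₂ (root gets 0).
    """
    n = chain.n_cells
    if not 0 <= root < n:
        raise ValueError(f"root {root} out of range for {n} cells")
    if n_components < 1 or n_components >= n:
        raise ValueError("n_components must lie in [1, n_cells)")
    W = chain.T.P + chain.T.P.T
    d = np.asarray(W.sum(axis=1)).ravel()
    d_is = 1.0 / np.sqrt(d)
    # rownorm(W) is similar to the symmetric D^{-1/2} W D^{-1/2}
    A = sp.diags(d_is) @ W @ sp.diags(d_is)
    lam, phi = np.linalg.eigh(np.asarray(A.todense()))
    order = np.argsort(-lam)
    lam, phi = lam[order], phi[:, order]
    # stationary eigenpair = eigenvalue closest to 1
    stat = int(np.argmin(np.abs(lam - 1.0)))
    keep = [i for i in range(len(lam)) if i != stat][:n_components]
    lam_k = lam[keep]
    if np.any(lam_k >= 1.0 - 1e-10):
        raise ValueError(
            "non-stationary eigenvalue numerically ≥ 1; the chain may be "
            "disconnected — try fewer components or check connectivity"
        )
    psi = sp.diags(d_is) @ phi[:, keep]  # right eigenvectors of rownorm(W)
    M = psi * (lam_k / (1.0 - lam_k))
    pt = np.linalg.norm(M - M[root], axis=1)
    return PseudotimeVector(values=pt, source="realtime_informed")
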