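"""Shared containers for the fate-mapping framework.

Everything downstream works with three objects: an annotated expression
matrix (:class:`ExpressionDataset`), a symmetric cell–cell similarity graph
(:class:`NeighborGraph`) and a row-stochastic Markov chain over cells
(:class:`TransitionMatrix`).  Kernels map a data view (pseudotime,
developmental potential, velocity, experimental time, metabolic labels)
onto a :class:`TransitionMatrix`; the estimator consumes it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

ROW_SUM_TOL = 1e-8

__all__ = [
    "ExpressionDataset",
    "NeighborGraph",
    "TransitionMatrix",
    "RandomWalk",
    "ROW_SUM_TOL",
]

# cell_meta / layer names with a fixed meaning across the package
RESERVED_LAYERS = ("X", "labeled", "total", "velocity")


def _as_dense(M) -> np.ndarray:
    if sp.issparse(M):
        return np.asarray(M.todense())
    return np.asarray(M)


@dataclass
class ExpressionDataset:
    """Annotated cell×gene expression matrix with layers and embeddings.

    Parameters
    ----------
    X
        Non-negative cell×gene matrix (counts or normalized), shape
        ``(n_cells, n_genes)``.  Dense ndarray or scipy sparse.
    cell_meta
        Per-cell table with ``n_cells`` rows.  Recognised columns:
        ``cluster`` (annotation label), ``time`` (experimental time point),
        ``labeling_time`` (labeling duration, hours) and ``experiment``
        (``pulse`` / ``chase`` / ``none``).
    gene_ids
        Length ``n_genes`` identifiers.
    layers
        Named matrices of identical shape (e.g. ``labeled``, ``total``,
        ``velocity``, ``X_smoothed``).
    embeddings
        Named per-cell coordinate matrices (e.g. ``pca``, ``umap``).
    """

    X: np.ndarray | sp.spmatrix
    cell_meta: pd.DataFrame
    gene_ids: np.ndarray
    layers: dict[str, np.ndarray | sp.spmatrix] = field(default_factory=dict)
    embeddings: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids)
        n_c, n_g = self.shape
        if len(self.gene_ids) != n_g:
            raise ValueError(
                f"gene_ids has {len(self.gene_ids)} entries for {n_g} genes"
            )
        if len(self.cell_meta) != n_c:
            raise ValueError(
                f"cell_meta has {len(self.cell_meta)} rows for {n_c} cells"
            )
        for name, layer in self.layers.items():
            if layer.shape != self.shape:
                raise ValueError(
                    f"layer {name!r} has shape {layer.shape}, expected {self.shape}"
                )
        for name, Z in self.embeddings.items():
            if Z.shape[0] != n_c:
                raise ValueError(
                    f"embedding {name!r} has {Z.shape[0]} rows for {n_c} cells"
                )
        Xd = self.X.data if sp.issparse(self.X) else np.asarray(self.X)
        if not np.all(np.isfinite(Xd)):
            raise ValueError("X contains non-finite values")
        if Xd.size and Xd.min() < 0:
            raise ValueError("X contains negative values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    @property
    def cell_ids(self) -> np.ndarray:
        return np.asarray(self.cell_meta.index.astype(str))

    def dense_X(self) -> np.ndarray:
        return _as_dense(self.X)

    def dense_layer(self, name: str) -> np.ndarray:
        if name == "X":
            return self.dense_X()
        return _as_dense(self.layers[name])

    def to_anndata(self):
        """Export to an :class:`anndata.AnnData` (h5ad dialect)."""
        import anndata as ad

        adata = ad.AnnData(
            X=sp.csr_matrix(self.X) if sp.issparse(self.X) else np.asarray(self.X, dtype=float),
            obs=self.cell_meta.copy(),
            var=pd.DataFrame(index=pd.Index(self.gene_ids.astype(str), name="gene_id")),
        )
        for name, layer in self.layers.items():
            adata.layers[name] = sp.csr_matrix(layer) if sp.issparse(layer) else np.asarray(layer, dtype=float)
        for name, Z in self.embeddings.items():
            adata.obsm[f"X_{name}"] = np.asarray(Z, dtype=float)
        return adata

    @classmethod
    def from_anndata(cls, adata) -> "ExpressionDataset":
        layers = {k: v for k, v in adata.layers.items()}
        embeddings = {
            k.removeprefix("X_"): np.asarray(v) for k, v in adata.obsm.items()
        }
        return cls(
            X=adata.X,
            cell_meta=adata.obs.copy(),
            gene_ids=np.asarray(adata.var_names),
            layers=layers,
            embeddings=embeddings,
        )


class NeighborGraph:
    """Sparse symmetric cell–cell similarity graph with weights ``w_jk``.

    The diagonal is zero; the cell itself is handled explicitly by the
    smoothing and kernel operations that need it.
    """

    def __init__(self, adjacency: sp.spmatrix):
        A = sp.csr_matrix(adjacency, copy=True)
        if A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        A.setdiag(0)
        A.eliminate_zeros()
        if A.nnz and A.data.min() < 0:
            raise ValueError("adjacency weights must be non-negative")
        degrees = np.diff(A.indptr)
        if np.any(degrees == 0):
            bad = np.flatnonzero(degrees == 0)
            raise ValueError(f"cells with empty neighborhoods: {bad.tolist()}")
        self.adjacency: sp.csr_matrix = A

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degree(self) -> np.ndarray:
        """Per-cell neighbor count k_j."""
        return np.diff(self.adjacency.indptr)

    def neighborhood(self, j: int) -> np.ndarray:
        """Index set N(j), excluding j itself."""
        A = self.adjacency
        return A.indices[A.indptr[j]: A.indptr[j + 1]]

    @classmethod
    def from_embedding(
        cls, coords: np.ndarray, n_neighbors: int = 15, mode: str = "connectivity"
    ) -> "NeighborGraph":
        """kNN graph on embedding coordinates, symmetrized by max(w, wᵀ).

        ``mode='connectivity'`` gives 0/1 weights; ``'distance'`` gives
        Gaussian-decayed weights exp(-d²/σ²) with σ the median kNN distance.
        """
        from sklearn.neighbors import kneighbors_graph

        coords = np.asarray(coords, dtype=float)
        G = kneighbors_graph(coords, n_neighbors, mode="distance", include_self=False)
        if mode == "connectivity":
            G.data[:] = 1.0
        elif mode == "distance":
            sigma = np.median(G.data) if G.nnz else 1.0
            G.data = np.exp(-(G.data**2) / max(sigma, 1e-12) ** 2)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        G = G.maximum(G.T)
        return cls(G)


class TransitionMatrix:
    """Sparse row-stochastic n_c×n_c Markov chain over cells.

    Invariants (checked on construction): entries ≥ 0, every row sums to 1
    within ``ROW_SUM_TOL``, no all-zero rows.  A matrix missing the row-sum
    tolerance is renormalized once and re-checked, then rejected.
    """

    def __init__(self, P: sp.spmatrix | np.ndarray, direction: str = "forward"):
        if direction not in ("forward", "backward"):
            raise ValueError(f"direction must be forward/backward, got {direction!r}")
        P = sp.csr_matrix(P, dtype=float)
        if P.shape[0] != P.shape[1]:
            raise ValueError("transition matrix must be square")
        if P.nnz and P.data.min() < 0:
            raise ValueError("transition probabilities must be non-negative")
        sums = np.asarray(P.sum(axis=1)).ravel()
        empty = np.flatnonzero(sums <= 0)
        if empty.size:
            raise ValueError(f"all-zero transition rows for cells: {empty.tolist()}")
        if np.max(np.abs(sums - 1.0)) > ROW_SUM_TOL:
            P = sp.diags(1.0 / sums) @ P
            sums = np.asarray(P.sum(axis=1)).ravel()
            if np.max(np.abs(sums - 1.0)) > ROW_SUM_TOL:
                raise ValueError("rows do not normalize to 1 within tolerance")
        self.P: sp.csr_matrix = sp.csr_matrix(P)
        self.direction = direction

    @property
    def n_cells(self) -> int:
        return self.P.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.P.shape

    def dense(self) -> np.ndarray:
        return np.asarray(self.P.todense())

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"TransitionMatrix(n_cells={self.n_cells}, nnz={self.P.nnz}, "
            f"direction={self.direction!r})"
        )


@dataclass
class RandomWalk:
    """A single realized random walk on a transition matrix."""

    states: np.ndarray
    stop_reason: str  # "max_steps" | "terminal_set"
    seed: int

    def __len__(self) -> int:
        return len(self.states)
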