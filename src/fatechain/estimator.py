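"""Macrostate and fate analysis of a cell–cell Markov chain.

The chain is coarse-grained into a small number of metastable macrostates
by generalized Perron cluster cluster analysis (GPCCA): the leading sorted
real Schur vectors of the transition matrix are rotated into a fuzzy
membership matrix χ on the probability simplex (inner-simplex
initialization followed by crispness-maximizing optimization).  Macrostates
with high coarse-grained self-transition probability are classified
terminal; initial states are the terminal states of the transposed chain.
Per-cell fate probabilities toward the terminal states are absorption
probabilities of the chain in which each terminal state's representative
cells are aggregated into a single absorbing pseudo-state — mathematically
equivalent to, and much faster than, absorbing toward the representative
cells one by one.

Two surfaces are provided: plain functions (:func:`compute_schur`,
:func:`compute_macrostates`, :func:`classify_states`,
:func:`compute_fate_probabilities`, :func:`rank_lineage_genes`,
:func:`gene_trend`) and a model/results pair (:class:`FateMap` /
:class:`FateMapResults`) that runs the whole analysis with one ``fit()``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy import stats
from scipy.linalg import schur as _schur, svd as _svd

from .datatypes import ExpressionDataset, NeighborGraph, TransitionMatrix
from .markov import backward_chain

__all__ = [
    "SchurDecomposition",
    "MacrostateDecomposition",
    "FateMatrix",
    "DriverRanking",
    "compute_schur",
    "compute_macrostates",
    "classify_states",
    "compute_fate_probabilities",
    "rank_lineage_genes",
    "gene_trend",
    "stationary_distribution",
    "FateMap",
    "FateMapResults",
]

DEFAULT_STABILITY = 0.96
DEFAULT_N_REPRESENTATIVES = 30


# ---------------------------------------------------------------------------
# Schur decomposition


@dataclass
class SchurDecomposition:
    """Leading sorted real Schur vectors of a transition matrix."""

    vectors: np.ndarray  # (n_cells, n_s)
    eigenvalues: np.ndarray  # complex, sorted by modulus descending
    _dense_T: np.ndarray = field(repr=False)
    _all_eigenvalues: np.ndarray = field(repr=False)

    @property
    def n_s(self) -> int:
        return self.vectors.shape[1]


def _sorted_eigenvalues(Td: np.ndarray) -> np.ndarray:
    ev = np.linalg.eigvals(Td)
    return ev[np.argsort(-np.abs(ev), kind="stable")]


def _select_count(ev_sorted: np.ndarray, n_s: int) -> int:
    """Grow n_s until a modulus gap separates selected from the rest.

    Conjugate pairs share a modulus, so a pair straddling the cut forces
    n_s up by one (reported by the caller).
    """
    n = len(ev_sorted)
    mods = np.abs(ev_sorted)
    while n_s < n and mods[n_s - 1] - mods[n_s] < 1e-9:
        n_s += 1
    return n_s


def _leading_schur_vectors(Td: np.ndarray, ev_sorted: np.ndarray, n_s: int) -> np.ndarray:
    mods = np.abs(ev_sorted)
    thresh = (mods[n_s - 1] + (mods[n_s] if n_s < len(mods) else -np.inf)) / 2.0
    if not np.isfinite(thresh):
        thresh = mods[n_s - 1] - 1e-12
    try:
        _, Z, sdim = _schur(
            Td, output="real", sort=lambda re_, im_: np.hypot(re_, im_) > thresh
        )
    except Exception as err:  # pragma: no cover
        raise RuntimeError(f"Schur decomposition failed: {err}") from err
    if sdim != n_s:
        # sorting by modulus can only disagree through numerically tied pairs
        n_s = sdim
    return Z[:, :n_s]


def compute_schur(T: TransitionMatrix, n_s: int) -> SchurDecomposition:
    """Top-``n_s`` sorted real Schur vectors of the chain.

    If the requested count would split a complex conjugate pair, ``n_s``
    is incremented by one and a warning issued.
    """
    if n_s < 2:
        raise ValueError("n_s must be ≥ 2")
    Td = T.dense()
    if n_s > Td.shape[0]:
        raise ValueError(f"n_s={n_s} exceeds the number of cells {Td.shape[0]}")
    ev = _sorted_eigenvalues(Td)
    n_eff = _select_count(ev, n_s)
    if n_eff != n_s:
        warnings.warn(
            f"n_s increased from {n_s} to {n_eff} to avoid splitting a "
            "complex conjugate pair",
            stacklevel=2,
        )
    Q = _leading_schur_vectors(Td, ev, n_eff)
    n_eff = Q.shape[1]
    return SchurDecomposition(
        vectors=Q,
        eigenvalues=ev[:n_eff],
        _dense_T=Td,
        _all_eigenvalues=ev,
    )


# ---------------------------------------------------------------------------
# GPCCA rotation


def _ones_first_basis(Q: np.ndarray) -> np.ndarray:
    """Orthonormal basis of span(Q), first column the constant vector.

    Returns X = √n · U with U orthonormal and X[:, 0] = 1, so that
    XᵀX = n·I.  Requires the ones vector to lie in the subspace (true
    whenever the λ=1 eigenvalue is among the selected ones).
    """
    n, m = Q.shape
    v = np.full(n, 1.0 / np.sqrt(n))
    resid = v - Q @ (Q.T @ v)
    if np.linalg.norm(resid) > 1e-6:
        raise ValueError(
            "the constant vector is not in the selected invariant subspace; "
            "is the leading eigenvalue 1?"
        )
    B = Q - np.outer(v, v @ Q)
    U, s, _ = _svd(B, full_matrices=False)
    X = np.column_stack([v, U[:, : m - 1]])
    return np.sqrt(n) * X


def _indexsearch(X: np.ndarray) -> np.ndarray:
    """Inner-simplex vertex search: m rows of X spanning the largest simplex."""
    n, m = X.shape
    ortho = X.copy()
    index = np.zeros(m, dtype=int)
    index[0] = int(np.argmax(np.linalg.norm(ortho, axis=1)))
    ortho = ortho - ortho[index[0]]
    for j in range(1, m):
        temp = ortho[index[j - 1]].copy()
        ortho = ortho - np.outer(ortho @ temp, temp)
        dists = np.linalg.norm(ortho, axis=1)
        index[j] = int(np.argmax(dists))
        maxdist = dists[index[j]]
        if maxdist <= 0:
            raise RuntimeError("degenerate Schur vectors in inner-simplex search")
        ortho = ortho / maxdist
    return index


def _fill_A(A: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Impose the feasibility constraints (χ ≥ 0, rows of χ sum to 1) on A."""
    m = A.shape[0]
    A = A.copy()
    if m > 1:
        A[1:, 0] = -A[1:, 1:].sum(axis=1)
        for j in range(m):
            A[0, j] = -(X[:, 1:] @ A[1:, j]).min()
    total = A[0].sum()
    if total <= 0:
        raise RuntimeError("infeasible rotation matrix in GPCCA optimization")
    return A / total


def _crispness(A: np.ndarray) -> float:
    """trace(D⁻¹ χᵀDχ) expressed through A; larger = crisper memberships."""
    return float(np.sum((A * A).sum(axis=0) / A[0]))


def _opt_soft(X: np.ndarray, A0: np.ndarray) -> tuple[np.ndarray, bool]:
    """Maximize crispness over the free (m−1)×(m−1) block of A."""
    from scipy.optimize import minimize

    m = A0.shape[0]
    if m < 3:
        # with two states the feasible set is essentially the initialization
        return _fill_A(A0, X), True

    def neg_obj(flat: np.ndarray) -> float:
        A = np.zeros((m, m))
        A[1:, 1:] = flat.reshape(m - 1, m - 1)
        try:
            A = _fill_A(A, X)
        except RuntimeError:
            return np.inf
        return -_crispness(A)

    x0 = A0[1:, 1:].ravel()
    res = minimize(
        neg_obj,
        x0,
        method="Nelder-Mead",
        options={"maxiter": 500 * (m - 1) ** 2, "xatol": 1e-8, "fatol": 1e-8},
    )
    A_init = _fill_A(A0, X)
    if not np.isfinite(res.fun) or -res.fun <= _crispness(A_init):
        warnings.warn(
            "GPCCA optimization did not improve over the inner-simplex "
            "initialization; returning the initialization",
            stacklevel=3,
        )
        return A_init, False
    A = np.zeros((m, m))
    A[1:, 1:] = res.x.reshape(m - 1, m - 1)
    return _fill_A(A, X), True


@dataclass
class MacrostateDecomposition:
    """Fuzzy macrostate memberships with a coarse-grained chain."""

    memberships: np.ndarray  # χ, (n_cells, m), rows on the simplex
    coarse_T: np.ndarray  # (m, m), row-stochastic
    assignments: np.ndarray  # argmax χ per cell
    top_cells: list[np.ndarray]  # per macrostate, ≤ n_f representative cells
    labels: list[str]
    n_representatives: int = DEFAULT_N_REPRESENTATIVES

    @property
    def n_states(self) -> int:
        return self.memberships.shape[1]


def stationary_distribution(T: TransitionMatrix) -> np.ndarray:
    """Left eigenvector for the eigenvalue closest to 1, normalized."""
    ev, V = np.linalg.eig(T.dense().T)
    i = int(np.argmin(np.abs(ev - 1.0)))
    pi = np.real(V[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _representatives(
    chi: np.ndarray, assignments: np.ndarray, n_f: int, order_by: np.ndarray | None = None
) -> list[np.ndarray]:
    """Per state, up to n_f assigned cells of highest membership.

    Ties break by cell index so builds are deterministic.
    """
    reps = []
    for s in range(chi.shape[1]):
        cells = np.flatnonzero(assignments == s)
        score = order_by[cells] if order_by is not None else chi[cells, s]
        order = np.lexsort((cells, -score))
        reps.append(cells[order[:n_f]])
    return reps


def compute_macrostates(
    schur: SchurDecomposition,
    m: int,
    n_f: int = DEFAULT_N_REPRESENTATIVES,
    T: TransitionMatrix | None = None,
    cluster_labels: np.ndarray | None = None,
) -> MacrostateDecomposition:
    """Rotate the leading ``m`` Schur vectors into macrostate memberships.

    ``m = 1`` is the degenerate single-macrostate case: all memberships are
    one, and representative cells are ranked by the chain's stationary
    distribution so the state reflects the chain's long-run behaviour.
    """
    n = schur._dense_T.shape[0]
    if m < 1:
        raise ValueError("m must be ≥ 1")
    if m > schur.n_s:
        raise ValueError(f"m={m} exceeds the available Schur vectors ({schur.n_s})")
    if m == 1:
        chi = np.ones((n, 1))
        pi = stationary_distribution(
            T if T is not None else TransitionMatrix(sp.csr_matrix(schur._dense_T))
        )
        assignments = np.zeros(n, dtype=int)
        reps = _representatives(chi, assignments, n_f, order_by=pi)
        labels = _name_states(reps, cluster_labels, 1)
        return MacrostateDecomposition(
            memberships=chi,
            coarse_T=np.ones((1, 1)),
            assignments=assignments,
            top_cells=reps,
            labels=labels,
            n_representatives=n_f,
        )
    m_eff = _select_count(schur._all_eigenvalues, m)
    if m_eff != m:
        warnings.warn(
            f"m increased from {m} to {m_eff} to avoid splitting a complex "
            "conjugate pair",
            stacklevel=2,
        )
        m = m_eff
    Q = _leading_schur_vectors(schur._dense_T, schur._all_eigenvalues, m)
    m = Q.shape[1]
    X = _ones_first_basis(Q)
    index = _indexsearch(X)
    A0 = np.linalg.inv(X[index])
    A, _ = _opt_soft(X, A0)
    chi = X @ A
    chi = np.clip(chi, 0.0, None)
    chi = chi / chi.sum(axis=1, keepdims=True)
    # coarse-grained chain with uniform weights: (χᵀχ)⁻¹ χᵀ T χ
    Td = schur._dense_T
    coarse = np.linalg.solve(chi.T @ chi, chi.T @ (Td @ chi))
    coarse = np.clip(coarse, 0.0, None)
    coarse = coarse / coarse.sum(axis=1, keepdims=True)
    assignments = np.argmax(chi, axis=1)
    reps = _representatives(chi, assignments, n_f)
    labels = _name_states(reps, cluster_labels, m)
    return MacrostateDecomposition(
        memberships=chi,
        coarse_T=coarse,
        assignments=assignments,
        top_cells=reps,
        labels=labels,
        n_representatives=n_f,
    )


def _name_states(
    reps: list[np.ndarray], cluster_labels: np.ndarray | None, m: int
) -> list[str]:
    """Majority cluster vote over representative cells; _1/_2 on ties."""
    if cluster_labels is None:
        return [f"state_{s}" for s in range(m)]
    cluster_labels = np.asarray(cluster_labels)
    raw = []
    for cells in reps:
        if cells.size == 0:
            raw.append("empty")
            continue
        vals, counts = np.unique(cluster_labels[cells].astype(str), return_counts=True)
        raw.append(vals[np.argmax(counts)])
    names, seen = [], {}
    for name in raw:
        if raw.count(name) > 1:
            seen[name] = seen.get(name, 0) + 1
            names.append(f"{name}_{seen[name]}")
        else:
            names.append(name)
    return names


def classify_states(
    decomp: MacrostateDecomposition, stability_threshold: float = DEFAULT_STABILITY
) -> dict[str, list[int]]:
    """Split macrostates by coarse self-transition probability.

    States with diagonal ≥ ``stability_threshold`` are terminal, the rest
    intermediate.  Initial states are obtained by running the same
    machinery on the backward chain (see :meth:`FateMap.fit`).
    """
    diag = np.diag(decomp.coarse_T)
    terminal = [int(i) for i in np.flatnonzero(diag >= stability_threshold)]
    if not terminal:
        warnings.warn(
            f"no macrostate has self-transition ≥ {stability_threshold}; "
            "empty terminal set returned",
            stacklevel=2,
        )
    intermediate = [i for i in range(decomp.n_states) if i not in terminal]
    return {"terminal": terminal, "intermediate": intermediate}


# ---------------------------------------------------------------------------
# Fate probabilities


@dataclass
class FateMatrix:
    """Per-cell absorption probabilities toward each terminal state."""

    probabilities: np.ndarray  # (n_cells, n_lineages)
    terminal_mask: np.ndarray  # True for cells inside a terminal set
    lineage_names: list[str]

    @property
    def n_lineages(self) -> int:
        return self.probabilities.shape[1]

    def to_frame(self, cell_ids=None) -> pd.DataFrame:
        idx = cell_ids if cell_ids is not None else np.arange(len(self.terminal_mask))
        return pd.DataFrame(self.probabilities, index=idx, columns=self.lineage_names)


def compute_fate_probabilities(
    T: TransitionMatrix,
    terminal_sets: list[np.ndarray],
    lineage_names: list[str] | None = None,
    tol: float = 1e-6,
) -> FateMatrix:
    """Absorption probabilities with per-lineage pseudo-state aggregation.

    Each terminal set is collapsed into one absorbing pseudo-state; the
    linear system (I − Q)F = S is solved per pseudo-state with a sparse
    iterative solver (GMRES with an incomplete-LU preconditioner, direct
    sparse fallback).  Aggregation before solving is mathematically
    equivalent to summing per-representative-cell absorption
    probabilities.
    """
    n = T.n_cells
    terminal_sets = [np.asarray(s, dtype=int) for s in terminal_sets]
    if not terminal_sets:
        raise ValueError("at least one terminal set is required")
    all_term = np.concatenate(terminal_sets)
    if len(np.unique(all_term)) != len(all_term):
        raise ValueError("terminal sets must be disjoint")
    terminal_mask = np.zeros(n, dtype=bool)
    terminal_mask[all_term] = True
    transient = np.flatnonzero(~terminal_mask)
    if transient.size == 0:
        raise ValueError("no transient cells: every cell is in a terminal set")

    P = T.P.tocsr()
    # reachability: every transient cell must reach some terminal cell
    reached = _reachable_from(P.T.tocsr(), all_term)
    stuck = [int(j) for j in transient if not reached[j]]
    if stuck:
        raise ValueError(
            f"transient cells with no path to any terminal set: {stuck}"
        )

    Q = P[np.ix_(transient, transient)].tocsc()
    A = (sp.eye(transient.size, format="csc") - Q).tocsc()
    S = np.column_stack(
        [np.asarray(P[np.ix_(transient, s)].sum(axis=1)).ravel() for s in terminal_sets]
    )
    F_trans = _solve_absorption(A, S, tol)
    probs = np.zeros((n, len(terminal_sets)))
    probs[transient] = F_trans
    for k, s in enumerate(terminal_sets):
        probs[s, k] = 1.0  # terminal cells are one-hot to their own state
    names = lineage_names or [f"lineage_{k}" for k in range(len(terminal_sets))]
    return FateMatrix(probabilities=probs, terminal_mask=terminal_mask, lineage_names=names)


def _reachable_from(P_rev: sp.csr_matrix, sources: np.ndarray) -> np.ndarray:
    from scipy.sparse.csgraph import breadth_first_order

    n = P_rev.shape[0]
    reached = np.zeros(n, dtype=bool)
    for s in sources:
        if reached[s]:
            continue
        order = breadth_first_order(P_rev, int(s), return_predecessors=False)
        reached[order] = True
    return reached


def _solve_absorption(A: sp.csc_matrix, S: np.ndarray, tol: float) -> np.ndarray:
    n = A.shape[0]
    F = np.zeros((n, S.shape[1]))
    try:
        ilu = spla.spilu(A.tocsc(), drop_tol=1e-6, fill_factor=20)
        M = spla.LinearOperator(A.shape, ilu.solve)
    except RuntimeError:
        M = None
    lu = None
    for k in range(S.shape[1]):
        x, info = spla.gmres(A, S[:, k], M=M, rtol=tol * 1e-2, atol=0.0, maxiter=2000)
        if info != 0:
            if lu is None:
                try:
                    lu = spla.splu(A)
                except RuntimeError as err:
                    raise RuntimeError(
                        f"absorption system is singular: {err}"
                    ) from err
            x = lu.solve(S[:, k])
        F[:, k] = x
    return F


# ---------------------------------------------------------------------------
# Lineage-correlated genes and trends


@dataclass
class DriverRanking:
    """Genes sorted by correlation of expression with a fate probability."""

    table: pd.DataFrame  # columns: gene_id, correlation[, pvalue, qvalue]
    lineage: str
    n_cells_used: int

    def top(self, k: int) -> np.ndarray:
        return self.table["gene_id"].to_numpy()[:k]


def rank_lineage_genes(
    X: np.ndarray,
    fate: FateMatrix,
    lineage: str,
    gene_ids: np.ndarray | None = None,
    cell_mask: np.ndarray | None = None,
    exclude_patterns: list[str] | None = None,
    compute_qvalues: bool = False,
) -> DriverRanking:
    """Rank genes by Pearson correlation with a lineage's fate column.

    Constant genes get correlation 0 (ranked below any positive
    correlate); a constant fate column under the mask is an error.
    Optional Benjamini–Hochberg q-values come from the correlation
    t-statistic with n−2 degrees of freedom.
    """
    X = np.asarray(X, dtype=float)
    n_c, n_g = X.shape
    gene_ids = (
        np.asarray(gene_ids) if gene_ids is not None else np.array([f"g{i}" for i in range(n_g)])
    )
    k = fate.lineage_names.index(lineage)
    mask = np.ones(n_c, dtype=bool) if cell_mask is None else np.asarray(cell_mask, dtype=bool)
    if mask.sum() < 3:
        raise ValueError("need at least 3 cells after masking")
    f = fate.probabilities[mask, k]
    if np.ptp(f) == 0:
        raise ValueError(f"fate column {lineage!r} has zero variance under the mask")
    keep = np.ones(n_g, dtype=bool)
    if exclude_patterns:
        pat = re.compile("|".join(exclude_patterns))
        keep = np.array([not pat.search(str(g)) for g in gene_ids])
    Xm = X[mask][:, keep]
    ids = gene_ids[keep]
    Xc = Xm - Xm.mean(axis=0)
    fc = f - f.mean()
    den = np.sqrt((Xc**2).sum(axis=0) * (fc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, (Xc.T @ fc) / np.where(den > 0, den, 1.0), 0.0)
    order = np.lexsort((np.arange(len(ids)), -r))  # stable, descending
    table = pd.DataFrame({"gene_id": ids[order], "correlation": r[order]})
    if compute_qvalues:
        nn = mask.sum()
        rr = np.clip(table["correlation"].to_numpy(), -0.9999999, 0.9999999)
        tstat = rr * np.sqrt((nn - 2) / (1.0 - rr**2))
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df=nn - 2)
        table["pvalue"] = pvals
        table["qvalue"] = _benjamini_hochberg(pvals)
    return DriverRanking(table=table, lineage=lineage, n_cells_used=int(mask.sum()))


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def _default_smoother(pt: np.ndarray, expr: np.ndarray, w: np.ndarray, grid: np.ndarray):
    """Weighted least-squares cubic spline; polynomial fallback on degenerate x."""
    from scipy.interpolate import make_lsq_spline

    pos = w > 0
    x, y, ww = pt[pos], expr[pos], w[pos]
    order = np.argsort(x, kind="stable")
    x, y, ww = x[order], y[order], ww[order]
    n_distinct = len(np.unique(x))
    if n_distinct >= 8:
        interior = np.quantile(x, [0.25, 0.5, 0.75])
        t = np.r_[[x[0]] * 4, interior, [x[-1]] * 4]
        try:
            spl = make_lsq_spline(x, y, t, k=3, w=ww)
            return spl(np.clip(grid, x[0], x[-1]))
        except Exception:
            pass
    deg = min(3, n_distinct - 1)
    coef = np.polyfit(x, y, deg, w=np.sqrt(ww))
    return np.polyval(coef, np.clip(grid, x[0], x[-1]))


def gene_trend(
    expr: np.ndarray,
    pt,
    weights: np.ndarray,
    smoother=None,
    grid_size: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Lineage-weighted expression trend on a uniform pseudotime grid.

    ``smoother`` is any callable ``(pt, expr, weights, grid) -> values``;
    the default is a weighted least-squares cubic spline.  Each cell's
    contribution is weighted by its fate probability toward the lineage.
    """
    pt_values = pt.values if hasattr(pt, "values") else np.asarray(pt, dtype=float)
    expr = np.asarray(expr, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if weights.min() < 0 or weights.max() > 1:
        raise ValueError("weights must lie in [0, 1]")
    if not np.any(weights > 0):
        raise ValueError("all lineage weights are zero")
    grid = np.linspace(pt_values.min(), pt_values.max(), grid_size)
    fn = smoother or _default_smoother
    return grid, np.asarray(fn(pt_values, expr, weights, grid))


# ---------------------------------------------------------------------------
# Model / Results


class FateMap:
    """Fate-mapping model over a cell–cell Markov chain.

    Parameters
    ----------
    transition_matrix
        Forward :class:`TransitionMatrix` produced by any kernel.
    dataset
        Optional :class:`ExpressionDataset`; enables macrostate naming
        (``cluster`` column), driver ranking and purity in the summary.
    cluster_key
        ``cell_meta`` column used for macrostate naming.
    """

    def __init__(
        self,
        transition_matrix: TransitionMatrix,
        dataset: ExpressionDataset | None = None,
        cluster_key: str = "cluster",
    ):
        self.T = transition_matrix
        self.dataset = dataset
        self.cluster_key = cluster_key

    def _cluster_labels(self) -> np.ndarray | None:
        if self.dataset is not None and self.cluster_key in self.dataset.cell_meta:
            return self.dataset.cell_meta[self.cluster_key].to_numpy()
        return None

    def fit(
        self,
        n_macrostates: int,
        n_schur: int | None = None,
        stability_threshold: float = DEFAULT_STABILITY,
        n_representatives: int = DEFAULT_N_REPRESENTATIVES,
        terminal_states: list[int] | None = None,
        compute_initial: bool = False,
        fate_tol: float = 1e-6,
    ) -> "FateMapResults":
        """Coarse-grain, classify states and compute fate probabilities.

        ``terminal_states`` overrides the automatic stability
        classification with user-chosen macrostate indices.
        """
        n_s = n_schur or max(n_macrostates, 2)
        schur = compute_schur(self.T, max(n_s, 2))
        decomp = compute_macrostates(
            schur,
            n_macrostates,
            n_f=n_representatives,
            T=self.T,
            cluster_labels=self._cluster_labels(),
        )
        if terminal_states is None:
            classes = classify_states(decomp, stability_threshold)
            terminal = classes["terminal"]
        else:
            terminal = list(terminal_states)
        fate = None
        if terminal:
            sets = [decomp.top_cells[s] for s in terminal]
            names = [decomp.labels[s] for s in terminal]
            try:
                fate = compute_fate_probabilities(self.T, sets, names, tol=fate_tol)
            except ValueError as err:
                warnings.warn(f"fate probabilities unavailable: {err}", stacklevel=2)
        initial = None
        if compute_initial:
            # initial states = terminal states of the transposed chain
            bwd = FateMap(backward_chain(self.T), self.dataset, self.cluster_key)
            bres = bwd.fit(
                n_macrostates,
                n_schur=n_schur,
                stability_threshold=stability_threshold,
                n_representatives=n_representatives,
            )
            initial = [bres.macrostates.top_cells[s] for s in bres.terminal_states]
        return FateMapResults(
            model=self,
            schur=schur,
            macrostates=decomp,
            terminal_states=terminal,
            fate=fate,
            initial_states=initial,
            stability_threshold=stability_threshold,
        )


@dataclass
class FateMapResults:
    """Fitted fate map: macrostates, state classes and fate probabilities."""

    model: FateMap
    schur: SchurDecomposition
    macrostates: MacrostateDecomposition
    terminal_states: list[int]
    fate: FateMatrix | None
    initial_states: list[np.ndarray] | None = None  # cell sets, backward chain
    stability_threshold: float = DEFAULT_STABILITY

    @property
    def terminal_sets(self) -> list[np.ndarray]:
        return [self.macrostates.top_cells[s] for s in self.terminal_states]

    @property
    def terminal_labels(self) -> list[str]:
        return [self.macrostates.labels[s] for s in self.terminal_states]

    def lineage_drivers(self, lineage: str, **kwargs) -> DriverRanking:
        if self.fate is None:
            raise ValueError("no fate probabilities were computed")
        if self.model.dataset is None:
            raise ValueError("driver ranking needs the expression dataset")
        ds = self.model.dataset
        return rank_lineage_genes(
            ds.dense_X(), self.fate, lineage, gene_ids=ds.gene_ids, **kwargs
        )

    def state_purity(self, state: int) -> float:
        """Percentage of the most abundant cluster among a state's top cells."""
        from .metrics import cell_type_purity

        labels = self.model._cluster_labels()
        if labels is None:
            raise ValueError("purity needs a cluster annotation")
        return cell_type_purity(self.macrostates.top_cells[state], labels)

    def summary(self) -> str:
        decomp = self.macrostates
        diag = np.diag(decomp.coarse_T)
        labels = self.model._cluster_labels()
        lines = [
            "Fate map summary",
            "=" * 64,
            f"cells: {self.model.T.n_cells}   macrostates: {decomp.n_states}   "
            f"stability threshold: {self.stability_threshold}",
            "-" * 64,
            f"{'state':<16}{'cells':>7}{'self-trans':>12}{'class':>14}"
            + ("{:>10}".format("purity") if labels is not None else ""),
        ]
        for s in range(decomp.n_states):
            n_cells = int((decomp.assignments == s).sum())
            cls = "terminal" if s in self.terminal_states else "intermediate"
            row = f"{decomp.labels[s]:<16}{n_cells:>7}{diag[s]:>12.4f}{cls:>14}"
            if labels is not None:
                row += f"{self.state_purity(s):>9.1f}%"
            lines.append(row)
        if self.fate is not None:
            lines.append("-" * 64)
            mean_fate = self.fate.probabilities[~self.fate.terminal_mask].mean(axis=0)
            fr = "  ".join(
                f"{n}={v:.3f}" for n, v in zip(self.fate.lineage_names, mean_fate)
            )
            lines.append(f"mean transient fate: {fr}")
        return "\n".join(lines)
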