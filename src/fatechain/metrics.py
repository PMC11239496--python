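"""Evaluation statistics for fate-mapping kernels and estimators.

TSI — terminal state identification score: area under the curve "number
of true terminal states identified vs. number of macrostates" relative to
the optimal step curve f_opt(n) = min(n, m).

CBC — cross-boundary correctness: for cells on the boundary between two
annotated states, the Pearson correlation between the kernel-implied
velocity T_j·X − x_j and the empirical neighbor-based velocity
Σ_{k∈N(j)∩C₂} w_jk (x_k − x_j).

Driver AUC — given a gene ranking and a curated driver set D, the count
φ(N) of drivers among the top N, summed over N and normalized by the
optimal area AUC* = |D|(|D|+1)/2 + (|G|−|D|)|D|.

Plus cell-type purity of a state's representative cells and per-lineage
fate-probability correlations (used to validate sparsification).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datatypes import NeighborGraph, TransitionMatrix
from .estimator import FateMatrix

__all__ = [
    "TerminalIdentificationCurve",
    "CbcResult",
    "DriverBenchmark",
    "optimal_identification_curve",
    "identification_curve",
    "tsi_score",
    "cbc_scores",
    "compare_kernels",
    "driver_auc",
    "cell_type_purity",
    "fate_correlation",
]


@dataclass
class TerminalIdentificationCurve:
    """f(n): terminal states identified with n macrostates, n = 1..N_max."""

    f: np.ndarray
    m: int  # true terminal state count
    N_max: int

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=int)
        if len(self.f) != self.N_max:
            raise ValueError(f"curve must have N_max={self.N_max} entries")
        if np.any(np.diff(self.f) < 0):
            raise ValueError("identification curve must be nondecreasing")
        if self.f.min() < 0 or np.any(self.f > np.minimum(np.arange(1, self.N_max + 1), self.m)):
            raise ValueError("curve must satisfy 0 ≤ f(n) ≤ min(n, m)")


def optimal_identification_curve(m: int, N_max: int) -> TerminalIdentificationCurve:
    """f_opt(n) = min(n, m): one new terminal state per added macrostate."""
    n = np.arange(1, N_max + 1)
    return TerminalIdentificationCurve(f=np.minimum(n, m), m=m, N_max=N_max)


def tsi_score(curve: TerminalIdentificationCurve) -> float:
    """TSI = Σ f(n) / Σ f_opt(n) over n = 1..N_max; 1 for an optimal kernel."""
    if curve.N_max < curve.m:
        raise ValueError(
            f"N_max={curve.N_max} < m={curve.m}: the optimal curve cannot saturate"
        )
    f_opt = np.minimum(np.arange(1, curve.N_max + 1), curve.m)
    return float(curve.f.sum() / f_opt.sum())


def identification_curve(
    macrostate_fn,
    terminal_labels,
    N_max: int,
    cell_labels: np.ndarray | None = None,
) -> TerminalIdentificationCurve:
    """Build the identification curve of a kernel on annotated data.

    A macrostate identifies a known terminal state when its
    majority-annotation label matches that state, mirroring how recovered
    macrostates are matched to known cell types.  ``macrostate_fn(n)``
    returns either the per-macrostate label list directly, or the
    per-macrostate representative-cell arrays (then ``cell_labels`` must
    supply the per-cell annotation for the majority vote).
    """
    terminal_labels = {str(t) for t in terminal_labels}
    m = len(terminal_labels)
    f = np.zeros(N_max, dtype=int)
    for n in range(1, N_max + 1):
        out = macrostate_fn(n)
        state_labels = []
        for item in out:
            if isinstance(item, str):
                state_labels.append(item)
            else:
                cells = np.asarray(item)
                if cells.size == 0:
                    continue
                if cell_labels is None:
                    raise ValueError(
                        "cell_labels is required when macrostate_fn returns cells"
                    )
                vals, counts = np.unique(
                    np.asarray(cell_labels)[cells].astype(str), return_counts=True
                )
                state_labels.append(vals[np.argmax(counts)])
        # tie-broken names ("X_1", "X_2") still identify terminal state X
        found = set()
        for lab in state_labels:
            if lab in terminal_labels:
                found.add(lab)
            else:
                base = re.sub(r"_\d+$", "", lab)
                if base in terminal_labels:
                    found.add(base)
        f[n - 1] = len(found)
    f = np.maximum.accumulate(f)  # identified states are never forgotten
    return TerminalIdentificationCurve(f=f, m=m, N_max=N_max)


# ---------------------------------------------------------------------------
# Cross-boundary correctness


@dataclass
class CbcResult:
    scores: np.ndarray  # β per usable boundary cell
    boundary_cells: np.ndarray
    n_dropped: int
    source: str = "C1"
    target: str = "C2"


def cbc_scores(
    T: TransitionMatrix,
    graph: NeighborGraph,
    X: np.ndarray,
    source: np.ndarray,
    target: np.ndarray,
) -> CbcResult:
    """CBC score per boundary cell of a known source→target transition.

    Boundary cells are source cells with ≥ 1 neighbor in the target set.
    Cells whose empirical or kernel velocity has zero variance are
    dropped and counted.
    """
    X = np.asarray(X, dtype=float)
    source = np.asarray(source, dtype=int)
    target = np.asarray(target, dtype=int)
    if np.intersect1d(source, target).size:
        raise ValueError("source and target sets must be disjoint")
    tset = set(target.tolist())
    W = graph.adjacency
    P = T.P
    cells, scores = [], []
    n_dropped = 0
    for j in source:
        nbrs = graph.neighborhood(j)
        in_tgt = np.array([k in tset for k in nbrs])
        if not in_tgt.any():
            continue
        w = np.asarray(W[j, nbrs[in_tgt]].todense()).ravel()
        v_emp = w @ (X[nbrs[in_tgt]] - X[j])
        v_ker = np.asarray(P[j].todense()).ravel() @ X - X[j]
        if np.ptp(v_emp) == 0 or np.ptp(v_ker) == 0:
            n_dropped += 1
            continue
        r = stats.pearsonr(v_emp, v_ker).statistic
        cells.append(j)
        scores.append(r)
    if not cells and n_dropped == 0:
        raise ValueError("empty boundary between source and target sets")
    if n_dropped:
        warnings.warn(f"{n_dropped} boundary cells dropped (zero variance)", stacklevel=2)
    return CbcResult(
        scores=np.asarray(scores),
        boundary_cells=np.asarray(cells, dtype=int),
        n_dropped=n_dropped,
    )


@dataclass
class KernelComparison:
    log_ratios: np.ndarray
    pvalue: float
    statistic: float
    n_excluded: int


def compare_kernels(cbc1: CbcResult, cbc2: CbcResult) -> KernelComparison:
    """Per-cell log CBC ratios and a one-sided Welch test (κ₁ > κ₂).

    Log ratios are defined only where both scores are positive; excluded
    cells are counted.  The Welch test is the two-sample unequal-variance
    t-test on the score arrays.
    """
    c1 = {int(c): s for c, s in zip(cbc1.boundary_cells, cbc1.scores)}
    c2 = {int(c): s for c, s in zip(cbc2.boundary_cells, cbc2.scores)}
    common = sorted(set(c1) & set(c2))
    ratios = []
    n_excluded = 0
    for c in common:
        if c1[c] > 0 and c2[c] > 0:
            ratios.append(np.log(c1[c] / c2[c]))
        else:
            n_excluded += 1
    if len(cbc1.scores) < 2 or len(cbc2.scores) < 2:
        raise ValueError("need at least 2 usable cells per kernel")
    res = stats.ttest_ind(
        cbc1.scores, cbc2.scores, equal_var=False, alternative="greater"
    )
    return KernelComparison(
        log_ratios=np.asarray(ratios),
        pvalue=float(res.pvalue),
        statistic=float(res.statistic),
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# Driver-ranking benchmark


@dataclass
class DriverBenchmark:
    phi: np.ndarray  # φ(N), N = 1..|G|
    auc: float
    auc_rel: float
    auc_star: float
    known: set = field(default_factory=set)


def driver_auc(ranking, known) -> DriverBenchmark:
    """Benchmark a gene ranking against a curated driver set.

    φ(N) = number of known drivers among the top N; AUC = Σ_N φ(N);
    AUC_rel = AUC / AUC* with AUC* the optimal-assignment area.
    """
    ranking = list(ranking)
    D = set(known)
    if not D:
        raise ValueError("the known-driver set is empty")
    missing = D - set(ranking)
    if missing:
        raise ValueError(f"known drivers absent from the ranking: {sorted(missing)}")
    G = len(ranking)
    d = len(D)
    hits = np.array([1 if g in D else 0 for g in ranking])
    phi = np.cumsum(hits)
    auc = float(phi.sum())
    auc_star = d * (d + 1) / 2.0 + (G - d) * d
    return DriverBenchmark(phi=phi, auc=auc, auc_rel=auc / auc_star, auc_star=auc_star, known=D)


def cell_type_purity(state_cells: np.ndarray, labels: np.ndarray) -> float:
    """Percentage of the most abundant annotation among a cell set."""
    state_cells = np.asarray(state_cells, dtype=int)
    if state_cells.size == 0:
        raise ValueError("state_cells must be non-empty")
    lab = np.asarray(labels)[state_cells].astype(str)
    _, counts = np.unique(lab, return_counts=True)
    return 100.0 * counts.max() / state_cells.size


def fate_correlation(F1: FateMatrix, F2: FateMatrix) -> dict[str, float]:
    """Per-lineage Pearson correlation between two fate matrices.

    Zero-variance columns yield NaN for that lineage (reported via
    warning) rather than an arbitrary value.
    """
    if F1.probabilities.shape != F2.probabilities.shape:
        raise ValueError("fate matrices cover different cells or lineages")
    if F1.lineage_names != F2.lineage_names:
        raise ValueError("lineage columns are not aligned")
    out: dict[str, float] = {}
    for k, name in enumerate(F1.lineage_names):
        a, b = F1.probabilities[:, k], F2.probabilities[:, k]
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            warnings.warn(f"zero-variance fate column {name!r}", stacklevel=2)
            out[name] = np.nan
            continue
        out[name] = float(stats.pearsonr(a, b).statistic)
    return out
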