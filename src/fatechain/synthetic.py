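"""Ground-truth-bearing synthetic fixtures for every module.

Each generator is a pure function of its parameters and a mandatory seed:
re-running with the same arguments is byte-identical.  The returned
:class:`SyntheticTruth` carries everything the evaluation statistics need
(planted branch, maturity, terminal cells, driver genes, kinetic rates),
so no external data are ever required.

The branching manifold places cells on a rooted tree in a 2-D latent
space: a trunk up to a split point, then ``n_branches`` diverging rays.
Gene programs come in three kinds — *decay* genes switching off at
per-gene maturity thresholds (so the expressed-gene count shrinks
monotonically with maturity, the signal the developmental-potential score
relies on), *driver* genes ramping up on one branch (the planted lineage
drivers), and shared ramp genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datatypes import ExpressionDataset, NeighborGraph, TransitionMatrix
from .labeling import labeled_abundance

__all__ = [
    "SyntheticTruth",
    "simulate_branching_manifold",
    "simulate_time_course",
    "simulate_pulse_chase",
    "planted_block_chain",
]

_SPLIT = 0.3  # maturity at which branches diverge
_DRIVER_ONSET = 0.35
_TERMINAL_MATURITY = 0.85


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a generated fixture."""

    seed: int
    params: dict
    branch: np.ndarray | None = None  # per-cell branch label (0 = trunk)
    maturity: np.ndarray | None = None  # per-cell progress in [0, 1]
    terminal_mask: np.ndarray | None = None
    driver_genes: dict[int, np.ndarray] = field(default_factory=dict)  # branch -> gene idx
    decay_genes: np.ndarray | None = None  # genes switching off with maturity
    alpha: np.ndarray | None = None  # per-cell × per-gene transcription rates
    gamma: np.ndarray | None = None
    r0: np.ndarray | None = None
    block: np.ndarray | None = None  # per-state planted block (chains)
    absorbing_blocks: list[int] = field(default_factory=list)

    def terminal_sets(self) -> list[np.ndarray]:
        """Per-branch terminal cell index arrays (branches in sorted order)."""
        out = []
        for b in np.unique(self.branch[self.terminal_mask]):
            out.append(
                np.flatnonzero((self.branch == b) & self.terminal_mask)
            )
        return out


def _sample_maturity(rng, n_cells: int, terminal_enrichment: float) -> np.ndarray:
    """Uniform progress with a pool of cells at the terminal attractors."""
    m = rng.uniform(0.0, 1.0, n_cells)
    pooled = rng.random(n_cells) < terminal_enrichment
    m[pooled] = rng.uniform(_TERMINAL_MATURITY, 1.0, int(pooled.sum()))
    return m


def _cluster_labels(maturity: np.ndarray, branch: np.ndarray) -> np.ndarray:
    """Annotation: root / branch_b / branch_b_tip (terminal region)."""
    lab = np.char.add("branch_", branch.astype(str))
    lab = np.where(maturity >= _TERMINAL_MATURITY, np.char.add(lab, "_tip"), lab)
    return np.where(maturity < _SPLIT, "root", lab)


def _tree_coords(maturity: np.ndarray, branch: np.ndarray, n_branches: int, rng) -> np.ndarray:
    scale = 5.0
    angles = (
        np.linspace(-np.pi / 3, np.pi / 3, n_branches)
        if n_branches > 1
        else np.array([0.0])
    )
    Z = np.zeros((len(maturity), 2))
    on_trunk = maturity < _SPLIT
    Z[on_trunk, 0] = maturity[on_trunk] * scale
    for b in range(n_branches):
        sel = (~on_trunk) & (branch == b)
        d = (maturity[sel] - _SPLIT) * scale
        Z[sel, 0] = _SPLIT * scale + d * np.cos(angles[b])
        Z[sel, 1] = d * np.sin(angles[b])
    Z += rng.normal(0.0, 0.08 * scale, Z.shape)
    return Z


def _gene_kinds(n_genes: int, n_branches: int, rng):
    """Partition genes into decay / per-branch driver / shared ramp."""
    n_decay = int(0.4 * n_genes)
    n_driver_total = max(n_branches, int(0.3 * n_genes))
    per_branch = max(2, n_driver_total // n_branches)
    idx = rng.permutation(n_genes)
    decay = np.sort(idx[:n_decay])
    drivers = {}
    pos = n_decay
    for b in range(n_branches):
        drivers[b] = np.sort(idx[pos: pos + per_branch])
        pos += per_branch
    shared = np.sort(idx[pos:])
    return decay, drivers, shared


def _expression_program(
    maturity: np.ndarray,
    branch: np.ndarray,
    n_genes: int,
    decay,
    drivers,
    shared,
    amp: np.ndarray,
    thr: np.ndarray,
) -> np.ndarray:
    n_c = len(maturity)
    X = np.zeros((n_c, n_genes))
    s = maturity[:, None]
    X[:, decay] = amp[decay] * (s <= thr[decay]) * (1.0 - 0.5 * s)
    for b, genes in drivers.items():
        ramp = np.clip((s - _DRIVER_ONSET) / (1.0 - _DRIVER_ONSET), 0.0, 1.0)
        on_branch = (branch == b)[:, None]
        X[:, genes] = amp[genes] * ramp * on_branch
    X[:, shared] = amp[shared] * (0.2 + 0.8 * s)
    return X


def simulate_branching_manifold(
    n_cells: int = 300,
    n_genes: int = 100,
    n_branches: int = 2,
    noise_sd: float = 0.1,
    seed: int = 0,
    n_neighbors: int = 15,
    terminal_enrichment: float = 0.25,
) -> tuple[ExpressionDataset, NeighborGraph, SyntheticTruth]:
    """Cells along a rooted tree with decay/driver/ramp gene programs.

    ``terminal_enrichment`` is the fraction of cells pooled in the
    terminal maturity band, emulating the accumulation of differentiated
    cells at stable attractors.
    """
    if n_branches < 1:
        raise ValueError("n_branches must be ≥ 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be ≥ 0")
    rng = np.random.default_rng(seed)
    maturity = _sample_maturity(rng, n_cells, terminal_enrichment)
    branch = rng.integers(0, n_branches, n_cells)
    branch[maturity < _SPLIT] = 0 if n_branches == 1 else branch[maturity < _SPLIT]
    decay, drivers, shared = _gene_kinds(n_genes, n_branches, rng)
    amp = rng.uniform(1.0, 3.0, n_genes)
    thr = rng.uniform(0.2, 1.0, n_genes)
    X = _expression_program(maturity, branch, n_genes, decay, drivers, shared, amp, thr)
    if noise_sd > 0:
        X = np.clip(X + rng.normal(0.0, noise_sd, X.shape), 0.0, None)
    Z = _tree_coords(maturity, branch, n_branches, rng)
    cluster = _cluster_labels(maturity, branch)
    meta = pd.DataFrame(
        {"cluster": cluster, "maturity": maturity},
        index=pd.Index([f"cell_{i}" for i in range(n_cells)], name="cell_id"),
    )
    ds = ExpressionDataset(
        X=X,
        cell_meta=meta,
        gene_ids=np.array([f"gene_{i}" for i in range(n_genes)]),
        embeddings={"latent": Z, "pca": Z},
    )
    graph = NeighborGraph.from_embedding(Z, n_neighbors=min(n_neighbors, n_cells - 1))
    truth = SyntheticTruth(
        seed=seed,
        params=dict(
            n_cells=n_cells, n_genes=n_genes, n_branches=n_branches, noise_sd=noise_sd
        ),
        branch=branch,
        maturity=maturity,
        terminal_mask=maturity >= _TERMINAL_MATURITY,
        driver_genes=drivers,
        decay_genes=decay,
    )
    return ds, graph, truth


def simulate_time_course(
    n_cells_per_time: int = 200,
    n_genes: int = 60,
    n_branches: int = 3,
    time_points: tuple = (0.0, 1.0, 2.0, 3.0),
    drift_per_step: float = 0.25,
    noise_sd: float = 0.1,
    seed: int = 0,
    n_neighbors: int = 15,
) -> tuple[ExpressionDataset, NeighborGraph, SyntheticTruth]:
    """Snapshots of a population drifting along the branching manifold.

    The maturity distribution advances by ``drift_per_step`` between
    consecutive snapshots, so optimal transport between them has a
    meaningful forward map; ``drift_per_step=0`` makes snapshots
    exchangeable.
    """
    if len(time_points) < 2:
        raise ValueError("need at least 2 time points")
    if n_cells_per_time < 1:
        raise ValueError("time points must be non-empty")
    rng = np.random.default_rng(seed)
    mats, branches, times = [], [], []
    for i, t in enumerate(time_points):
        center = 0.1 + drift_per_step * i
        m = np.clip(rng.normal(center, 0.12, n_cells_per_time), 0.0, 1.0)
        b = rng.integers(0, n_branches, n_cells_per_time)
        mats.append(m)
        branches.append(b)
        times.append(np.full(n_cells_per_time, float(t)))
    maturity = np.concatenate(mats)
    branch = np.concatenate(branches)
    time = np.concatenate(times)
    decay, drivers, shared = _gene_kinds(n_genes, n_branches, rng)
    amp = rng.uniform(1.0, 3.0, n_genes)
    thr = rng.uniform(0.2, 1.0, n_genes)
    X = _expression_program(maturity, branch, n_genes, decay, drivers, shared, amp, thr)
    if noise_sd > 0:
        X = np.clip(X + rng.normal(0.0, noise_sd, X.shape), 0.0, None)
    Z = _tree_coords(maturity, branch, n_branches, rng)
    n_total = len(maturity)
    cluster = _cluster_labels(maturity, branch)
    meta = pd.DataFrame(
        {"cluster": cluster, "maturity": maturity, "time": time},
        index=pd.Index([f"cell_{i}" for i in range(n_total)], name="cell_id"),
    )
    ds = ExpressionDataset(
        X=X,
        cell_meta=meta,
        gene_ids=np.array([f"gene_{i}" for i in range(n_genes)]),
        embeddings={"latent": Z, "pca": Z},
    )
    graph = NeighborGraph.from_embedding(Z, n_neighbors=min(n_neighbors, n_total - 1))
    truth = SyntheticTruth(
        seed=seed,
        params=dict(
            n_cells_per_time=n_cells_per_time,
            n_genes=n_genes,
            n_branches=n_branches,
            time_points=tuple(time_points),
            drift_per_step=drift_per_step,
            noise_sd=noise_sd,
        ),
        branch=branch,
        maturity=maturity,
        terminal_mask=maturity >= _TERMINAL_MATURITY,
        driver_genes=drivers,
        decay_genes=decay,
    )
    return ds, graph, truth


def _alpha_field(
    maturity: np.ndarray,
    branch: np.ndarray,
    base: np.ndarray,
    decay,
    drivers,
) -> np.ndarray:
    """Per-cell transcription rates: drivers ramp up on-branch, decay genes fall."""
    n_c, n_g = len(maturity), len(base)
    A = np.tile(base, (n_c, 1))
    s = maturity[:, None]
    A[:, decay] = base[decay] * np.clip(1.2 - s, 0.2, None)
    for b, genes in drivers.items():
        ramp = np.clip((s - _DRIVER_ONSET) / (1.0 - _DRIVER_ONSET), 0.0, 1.0)
        on_branch = (branch == b)[:, None].astype(float)
        A[:, genes] = base[genes] * (0.2 + 2.8 * ramp * on_branch)
    return A


def simulate_pulse_chase(
    n_cells: int = 240,
    n_genes: int = 30,
    alpha_range: tuple = (0.5, 5.0),
    gamma_range: tuple = (0.2, 2.0),
    durations_pulse: tuple = (0.5, 1.0, 2.0),
    durations_chase: tuple = (),
    noise_model: str = "poisson",
    seed: int = 0,
    n_branches: int = 2,
    maturation_lag: float = 0.25,
    terminal_enrichment: float = 0.25,
) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Pulse/chase labeled + total count layers from planted (α, γ).

    Per-cell transcription rates follow the branching manifold: driver
    genes have elevated α on their branch (ramping with maturity), decay
    genes fall off.  Total RNA lags its moving steady state by
    ``maturation_lag`` in maturity units, so rate-derived velocities point
    along the manifold.  ``noise_model='none'`` makes the labeled layer
    equal the closed forms exactly; ``'poisson'`` draws counts.
    """
    if durations_pulse and len(set(durations_pulse)) < 2:
        raise ValueError("pulse arm requires at least 2 distinct durations")
    if durations_chase and len(set(durations_chase)) < 3:
        raise ValueError("chase arm requires at least 3 distinct durations")
    if not durations_pulse and not durations_chase:
        raise ValueError("at least one experimental arm is required")
    if noise_model not in ("none", "poisson"):
        raise ValueError(f"unknown noise model {noise_model!r}")
    rng = np.random.default_rng(seed)
    maturity = _sample_maturity(rng, n_cells, terminal_enrichment)
    branch = rng.integers(0, n_branches, n_cells)
    decay, drivers, shared = _gene_kinds(n_genes, n_branches, rng)
    base_alpha = rng.uniform(*alpha_range, n_genes)
    gamma_g = rng.uniform(*gamma_range, n_genes)
    alpha = _alpha_field(maturity, branch, base_alpha, decay, drivers)
    gamma = np.tile(gamma_g, (n_cells, 1))
    # total RNA lags the moving steady state -> non-zero velocity α − γr
    alpha_lagged = _alpha_field(
        np.clip(maturity - maturation_lag, 0.0, 1.0), branch, base_alpha, decay, drivers
    )
    total = alpha_lagged / gamma

    kinds = []
    taus = []
    arms = []
    if durations_pulse:
        arms.append(("pulse", list(durations_pulse)))
    if durations_chase:
        arms.append(("chase", list(durations_chase)))
    for i in range(n_cells):
        arm, durs = arms[i % len(arms)]
        kinds.append(arm)
        taus.append(durs[(i // len(arms)) % len(durs)])
    kinds = np.asarray(kinds, dtype=object)
    taus = np.asarray(taus, dtype=float)

    labeled = np.zeros((n_cells, n_genes))
    r0 = total.copy()  # chase wash-out starts from the current total
    for i in range(n_cells):
        if kinds[i] == "pulse":
            labeled[i] = labeled_abundance("pulse", taus[i], alpha[i], gamma[i])
        else:
            labeled[i] = labeled_abundance(
                "chase_labeled", taus[i], alpha[i], gamma[i], r0=r0[i]
            )
    if noise_model == "poisson":
        labeled_obs = rng.poisson(labeled).astype(float)
        total_obs = rng.poisson(total).astype(float)
    else:
        labeled_obs, total_obs = labeled, total

    Z = _tree_coords(maturity, branch, n_branches, rng)
    cluster = _cluster_labels(maturity, branch)
    meta = pd.DataFrame(
        {
            "cluster": cluster,
            "maturity": maturity,
            "experiment": kinds,
            "labeling_time": taus,
        },
        index=pd.Index([f"cell_{i}" for i in range(n_cells)], name="cell_id"),
    )
    ds = ExpressionDataset(
        X=total_obs,
        cell_meta=meta,
        gene_ids=np.array([f"gene_{i}" for i in range(n_genes)]),
        layers={"labeled": labeled_obs, "total": total_obs},
        embeddings={"latent": Z, "pca": Z},
    )
    truth = SyntheticTruth(
        seed=seed,
        params=dict(
            n_cells=n_cells,
            n_genes=n_genes,
            alpha_range=alpha_range,
            gamma_range=gamma_range,
            durations_pulse=tuple(durations_pulse),
            durations_chase=tuple(durations_chase),
            noise_model=noise_model,
            n_branches=n_branches,
            maturation_lag=maturation_lag,
        ),
        branch=branch,
        maturity=maturity,
        terminal_mask=maturity >= _TERMINAL_MATURITY,
        driver_genes=drivers,
        decay_genes=decay,
        alpha=alpha,
        gamma=gamma,
        r0=r0,
    )
    return ds, truth


def planted_block_chain(
    block_sizes: list[int],
    leakage_eps: float = 0.01,
    absorbing_blocks: list[int] | None = None,
    seed: int = 0,
    leak_weights: dict[int, dict[int, float]] | None = None,
    allow_disconnected: bool = False,
) -> tuple[TransitionMatrix, SyntheticTruth]:
    """Row-stochastic chain with planted metastable blocks.

    Each non-absorbing block keeps mass 1−ε uniformly within itself and
    leaks ε along the block digraph (default: uniformly to the absorbing
    blocks, or to all other blocks when none are absorbing).  Absorbing
    blocks are self-contained.  Leak targets can be overridden per block
    with ``leak_weights``.
    """
    if not 0.0 <= leakage_eps < 0.5:
        raise ValueError("leakage_eps must lie in [0, 0.5)")
    absorbing_blocks = list(absorbing_blocks or [])
    n_blocks = len(block_sizes)
    block = np.concatenate(
        [np.full(sz, b, dtype=int) for b, sz in enumerate(block_sizes)]
    )
    n = len(block)
    members = [np.flatnonzero(block == b) for b in range(n_blocks)]
    rng = np.random.default_rng(seed)
    T = np.zeros((n, n))

    def _within(idx: np.ndarray, mass: float) -> np.ndarray:
        w = rng.uniform(0.5, 1.5, (len(idx), len(idx)))
        return mass * w / w.sum(axis=1, keepdims=True)

    for b in range(n_blocks):
        idx = members[b]
        if b in absorbing_blocks or leakage_eps == 0.0:
            T[np.ix_(idx, idx)] = _within(idx, 1.0)
            continue
        if leak_weights and b in leak_weights:
            targets = {t: w for t, w in leak_weights[b].items() if t != b and w > 0}
        elif absorbing_blocks:
            targets = {a: 1.0 for a in absorbing_blocks}
        else:
            targets = {o: 1.0 for o in range(n_blocks) if o != b}
        if not targets:  # self-contained non-absorbing block
            T[np.ix_(idx, idx)] = _within(idx, 1.0)
            continue
        total_w = sum(targets.values())
        T[np.ix_(idx, idx)] = _within(idx, 1.0 - leakage_eps)
        for tgt, w in targets.items():
            tidx = members[tgt]
            T[np.ix_(idx, tidx)] = leakage_eps * (w / total_w) / len(tidx)
    if absorbing_blocks and not allow_disconnected:
        from scipy.sparse.csgraph import breadth_first_order

        P_rev = sp.csr_matrix(T).T.tocsr()
        reached = np.zeros(n, dtype=bool)
        for a in absorbing_blocks:
            for s_ in members[a]:
                if not reached[s_]:
                    order = breadth_first_order(P_rev, int(s_), return_predecessors=False)
                    reached[order] = True
        if not reached.all():
            bad_blocks = sorted(set(block[~reached].tolist()))
            raise ValueError(
                f"blocks with no path to any absorbing block: {bad_blocks}"
            )
    truth = SyntheticTruth(
        seed=seed,
        params=dict(
            block_sizes=list(block_sizes),
            leakage_eps=leakage_eps,
            absorbing_blocks=absorbing_blocks,
        ),
        block=block,
        absorbing_blocks=absorbing_blocks,
    )
    return TransitionMatrix(sp.csr_matrix(T)), truth
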