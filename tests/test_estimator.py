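"""Coarse-graining estimator: Schur, macrostates, classification, fates."""

import numpy as np
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

from fatechain.datatypes import TransitionMatrix
from fatechain.estimator import (
    FateMap,
    classify_states,
    compute_fate_probabilities,
    compute_macrostates,
    compute_schur,
    gene_trend,
    rank_lineage_genes,
)
from fatechain.markov import row_normalize
from fatechain.synthetic import planted_block_chain


class TestComputeSchur:
    def test_disconnected_blocks_have_two_unit_eigenvalues(self):
        T, _ = planted_block_chain([10, 10], leakage_eps=0.0, seed=0)
        schur = compute_schur(T, 2)
        np.testing.assert_allclose(np.abs(schur.eigenvalues), [1.0, 1.0], atol=1e-10)

    def test_two_state_chain_closed_form_eigenvalues(self):
        T = TransitionMatrix(np.array([[0.9, 0.1], [0.1, 0.9]]))
        schur = compute_schur(T, 2)
        np.testing.assert_allclose(
            sorted(np.real(schur.eigenvalues), reverse=True), [1.0, 0.8], atol=1e-12
        )

    def test_complex_pair_not_split(self):
        # 3-cycle with noise: complex conjugate pair below the stationary one
        P = 0.9 * np.roll(np.eye(3), 1, axis=1) + 0.1 / 3
        T = TransitionMatrix(P)
        with pytest.warns(UserWarning, match="complex conjugate"):
            schur = compute_schur(T, 2)
        assert schur.n_s == 3

    def test_vectors_orthonormal(self):
        T, _ = planted_block_chain([15, 15, 15], leakage_eps=0.05, seed=1)
        schur = compute_schur(T, 3)
        np.testing.assert_allclose(
            schur.vectors.T @ schur.vectors, np.eye(3), atol=1e-8
        )


class TestComputeMacrostates:
    def test_recovers_planted_blocks(self):
        T, truth = planted_block_chain([40, 30, 30], leakage_eps=0.01, seed=2)
        schur = compute_schur(T, 3)
        decomp = compute_macrostates(schur, 3)
        assert adjusted_rand_score(truth.block, decomp.assignments) == 1.0

    def test_disconnected_blocks_give_indicator_memberships(self):
        T, truth = planted_block_chain([12, 8], leakage_eps=0.0, seed=3)
        schur = compute_schur(T, 2)
        decomp = compute_macrostates(schur, 2)
        chi = decomp.memberships
        hard = np.zeros_like(chi)
        hard[np.arange(len(truth.block)), decomp.assignments] = 1.0
        np.testing.assert_allclose(chi, hard, atol=1e-8)
        np.testing.assert_allclose(decomp.coarse_T, np.eye(2), atol=1e-8)

    def test_membership_rows_on_simplex(self):
        T, _ = planted_block_chain([20, 20, 20], leakage_eps=0.05, seed=4)
        decomp = compute_macrostates(compute_schur(T, 3), 3)
        assert decomp.memberships.min() >= 0
        np.testing.assert_allclose(decomp.memberships.sum(axis=1), 1.0, atol=1e-8)
        np.testing.assert_allclose(decomp.coarse_T.sum(axis=1), 1.0, atol=1e-8)

    def test_single_macrostate_ranks_by_stationary_mass(self):
        T, truth = planted_block_chain([20, 20], leakage_eps=0.1, absorbing_blocks=[1], seed=5)
        decomp = compute_macrostates(compute_schur(T, 2), 1, n_f=10, T=T)
        # the stationary distribution lives on the absorbing block
        assert set(decomp.top_cells[0]) <= set(np.flatnonzero(truth.block == 1))


class TestClassifyStates:
    def test_absorbing_block_is_terminal(self):
        T, truth = planted_block_chain([25, 25], leakage_eps=0.05, absorbing_blocks=[1], seed=6)
        decomp = compute_macrostates(compute_schur(T, 2), 2)
        classes = classify_states(decomp)
        terminal_blocks = {
            int(np.median(truth.block[decomp.assignments == s]))
            for s in classes["terminal"]
        }
        assert terminal_blocks == {1}

    def test_threshold_reads_coarse_diagonal(self):
        from fatechain.estimator import MacrostateDecomposition

        decomp = MacrostateDecomposition(
            memberships=np.ones((4, 2)) * 0.5,
            coarse_T=np.array([[0.99, 0.01], [0.3, 0.7]]),
            assignments=np.array([0, 0, 1, 1]),
            top_cells=[np.array([0, 1]), np.array([2, 3])],
            labels=["a", "b"],
        )
        assert classify_states(decomp, 0.96)["terminal"] == [0]

    def test_unreachable_threshold_warns_and_returns_empty(self):
        T, _ = planted_block_chain([15, 15], leakage_eps=0.1, seed=7)
        decomp = compute_macrostates(compute_schur(T, 2), 2)
        with pytest.warns(UserWarning, match="no macrostate"):
            classes = classify_states(decomp, 1.01)
        assert classes["terminal"] == []


class TestFateProbabilities:
    def test_one_step_absorption(self):
        P = np.array(
            [[0.0, 0.3, 0.7], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
        )
        F = compute_fate_probabilities(
            TransitionMatrix(P), [np.array([1]), np.array([2])]
        )
        np.testing.assert_allclose(F.probabilities[0], [0.3, 0.7], atol=1e-8)

    def test_self_loop_renormalizes_escape_mass(self):
        P = np.array(
            [[0.5, 0.25, 0.25], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
        )
        F = compute_fate_probabilities(
            TransitionMatrix(P), [np.array([1]), np.array([2])]
        )
        np.testing.assert_allclose(F.probabilities[0], [0.5, 0.5], atol=1e-8)

    def test_terminal_cells_are_one_hot(self):
        T, truth = planted_block_chain(
            [20, 15, 15], leakage_eps=0.1, absorbing_blocks=[1, 2], seed=8
        )
        sets = [np.flatnonzero(truth.block == b) for b in (1, 2)]
        F = compute_fate_probabilities(T, sets)
        np.testing.assert_allclose(F.probabilities[sets[0], 0], 1.0)
        np.testing.assert_allclose(F.probabilities[sets[0], 1], 0.0)

    def test_aggregated_pseudo_state_equals_per_cell_sum(self):
        """Absorbing toward one aggregated pseudo-state must match summing
        absorption probabilities over the individual representative cells."""
        rng = np.random.default_rng(9)
        P = rng.random((12, 12)) + 0.05
        for j in (9, 10, 11):
            P[j] = 0.0
            P[j, j] = 1.0
        T = TransitionMatrix(sp.csr_matrix(P / P.sum(axis=1, keepdims=True)))
        agg = compute_fate_probabilities(T, [np.array([9, 10, 11])])
        per_cell = compute_fate_probabilities(
            T, [np.array([9]), np.array([10]), np.array([11])]
        )
        np.testing.assert_allclose(
            agg.probabilities[:9, 0], per_cell.probabilities[:9].sum(axis=1), atol=1e-8
        )

    def test_matches_dense_oracle_on_random_chains(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            n = int(rng.integers(10, 60))
            P = rng.random((n, n)) ** 3 + 1e-3
            k = int(rng.integers(2, 4))
            absorbing = rng.choice(n, size=k, replace=False)
            for j in absorbing:
                P[j] = 0.0
                P[j, j] = 1.0
            P = P / P.sum(axis=1, keepdims=True)
            T = TransitionMatrix(sp.csr_matrix(P))
            sets = [np.array([j]) for j in absorbing]
            F = compute_fate_probabilities(T, sets)
            transient = np.setdiff1d(np.arange(n), absorbing)
            Q = P[np.ix_(transient, transient)]
            S = P[np.ix_(transient, absorbing)]
            F_dense = np.linalg.solve(np.eye(len(transient)) - Q, S)
            np.testing.assert_allclose(
                F.probabilities[transient], F_dense, atol=1e-6
            )

    def test_lumping_terminal_sets_sums_columns(self):
        T, truth = planted_block_chain(
            [20, 15, 15], leakage_eps=0.1, absorbing_blocks=[1, 2], seed=11
        )
        sets = [np.flatnonzero(truth.block == b) for b in (1, 2)]
        split = compute_fate_probabilities(T, sets)
        merged = compute_fate_probabilities(T, [np.concatenate(sets)])
        np.testing.assert_allclose(
            merged.probabilities[:20, 0], split.probabilities[:20].sum(axis=1), atol=1e-8
        )

    def test_stranded_transient_cell_reported(self):
        P = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0], [0.0, 0.0, 1.0]])
        with pytest.raises(ValueError, match=r"no path.*\[0\]"):
            compute_fate_probabilities(TransitionMatrix(P), [np.array([2])])

    def test_overlapping_terminal_sets_rejected(self, tiny_chain):
        with pytest.raises(ValueError, match="disjoint"):
            compute_fate_probabilities(tiny_chain, [np.array([0]), np.array([0, 1])])


class TestDriverRanking:
    def _fate(self, values):
        from fatechain.estimator import FateMatrix

        v = np.asarray(values, dtype=float)[:, None]
        return FateMatrix(
            probabilities=np.column_stack([v, 1 - v]),
            terminal_mask=np.zeros(len(v), bool),
            lineage_names=["a", "b"],
        )

    def test_fate_column_itself_ranks_first(self):
        rng = np.random.default_rng(0)
        f = rng.random(50)
        X = np.column_stack([rng.random((50, 5)), f])
        r = rank_lineage_genes(X, self._fate(f), "a")
        assert r.table.iloc[0]["gene_id"] == "g5"
        assert r.table.iloc[0]["correlation"] == pytest.approx(1.0)

    def test_constant_gene_gets_zero_correlation(self):
        rng = np.random.default_rng(1)
        f = rng.random(30)
        X = np.column_stack([np.full(30, 2.0), f])
        r = rank_lineage_genes(X, self._fate(f), "a")
        tab = r.table.set_index("gene_id")
        assert tab.loc["g0", "correlation"] == 0.0
        assert tab.index[0] == "g1"

    def test_planted_drivers_outrank_permuted_genes(self):
        rng = np.random.default_rng(2)
        f = rng.random(100)
        drivers = f[:, None] * rng.uniform(0.5, 2, 3) + 0.1 * rng.normal(size=(100, 3))
        noise = rng.permutation(f)[:, None] * np.ones(4) + 0.1 * rng.normal(size=(100, 4))
        X = np.column_stack([noise, drivers])
        r = rank_lineage_genes(X, self._fate(f), "a")
        assert set(r.top(3)) == {"g4", "g5", "g6"}

    def test_exclusion_patterns_drop_genes(self):
        rng = np.random.default_rng(3)
        f = rng.random(30)
        X = np.column_stack([f, f])
        r = rank_lineage_genes(
            X,
            self._fate(f),
            "a",
            gene_ids=np.array(["mt-co1", "Gata1"]),
            exclude_patterns=["^mt-"],
        )
        assert list(r.table["gene_id"]) == ["Gata1"]

    def test_qvalues_monotone_in_pvalues(self):
        rng = np.random.default_rng(4)
        f = rng.random(40)
        X = rng.random((40, 6))
        r = rank_lineage_genes(X, self._fate(f), "a", compute_qvalues=True)
        tab = r.table.sort_values("pvalue")
        assert np.all(np.diff(tab["qvalue"]) >= -1e-12)

    def test_zero_variance_fate_rejected(self):
        X = np.random.default_rng(5).random((10, 3))
        with pytest.raises(ValueError, match="zero variance"):
            rank_lineage_genes(X, self._fate(np.full(10, 0.5)), "a")


class TestGeneTrend:
    def test_constant_expression_gives_constant_curve(self):
        pt = np.linspace(0, 1, 50)
        grid, curve = gene_trend(np.full(50, 2.5), pt, np.ones(50))
        np.testing.assert_allclose(curve, 2.5, atol=1e-8)

    def test_linear_expression_recovered(self):
        pt = np.linspace(0, 1, 100)
        expr = 3.0 * pt + 1.0
        grid, curve = gene_trend(expr, pt, np.ones(100))
        np.testing.assert_allclose(curve, 3.0 * grid + 1.0, atol=1e-2)

    def test_curve_depends_only_on_weighted_cells(self):
        rng = np.random.default_rng(0)
        pt = np.linspace(0, 1, 60)
        expr = rng.random(60)
        w = np.zeros(60)
        w[:30] = 1.0
        _, c1 = gene_trend(expr, pt, w)
        expr2 = expr.copy()
        expr2[30:] = 99.0  # unweighted cells change, curve must not
        _, c2 = gene_trend(expr2, pt, w)
        np.testing.assert_allclose(c1, c2)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            gene_trend(np.ones(5), np.linspace(0, 1, 5), np.zeros(5))


class TestFateMapModel:
    def test_fit_classifies_and_computes_fates(self):
        T, truth = planted_block_chain(
            [30, 25, 25], leakage_eps=0.05, absorbing_blocks=[1, 2], seed=12
        )
        res = FateMap(T).fit(3)
        assert len(res.terminal_states) == 2
        fates = res.fate.probabilities[truth.block == 0]
        np.testing.assert_allclose(fates.sum(axis=1), 1.0, atol=1e-6)
        assert "Fate map summary" in res.summary()

    def test_backward_fit_flags_planted_source_as_initial(self):
        # source block leaks forward into an absorbing sink
        T, truth = planted_block_chain(
            [25, 25], leakage_eps=0.1, absorbing_blocks=[1], seed=13
        )
        res = FateMap(T).fit(2, compute_initial=True, stability_threshold=0.95)
        assert res.initial_states is not None and len(res.initial_states) >= 1
        source_cells = set(np.flatnonzero(truth.block == 0).tolist())
        for cells in res.initial_states:
            assert set(cells.tolist()) <= source_cells

    def test_user_override_of_terminal_states(self):
        T, _ = planted_block_chain(
            [20, 20], leakage_eps=0.1, absorbing_blocks=[1], seed=14
        )
        res = FateMap(T).fit(2, terminal_states=[0, 1])
        assert res.terminal_states == [0, 1]
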