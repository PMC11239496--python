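"""Metabolic-labeling kinetics: closed forms, neighborhoods, rate fitting."""

import numpy as np
import pytest

from fatechain.labeling import (
    LabelingDesign,
    fit_kinetic_rates,
    fit_rate_curve,
    labeled_abundance,
    rates_to_velocity,
    select_labeling_neighborhoods,
)
from fatechain.synthetic import simulate_pulse_chase


class TestLabeledAbundance:
    def test_pulse_starts_at_zero(self):
        assert labeled_abundance("pulse", 0.0, 2.0, 1.0) == 0.0

    def test_pulse_half_saturation(self):
        assert labeled_abundance("pulse", np.log(2), 2.0, 1.0) == pytest.approx(1.0)

    def test_chase_labeled_hand_value(self):
        out = labeled_abundance("chase_labeled", np.log(2), 2.0, 1.0, r0=5.0)
        assert out == pytest.approx(4.0)

    def test_pulse_saturates_at_steady_state(self):
        assert labeled_abundance("pulse", 1e6, 2.0, 1.0) == pytest.approx(2.0)

    def test_pulse_and_chase_unlabeled_share_closed_form(self):
        tau = np.linspace(0, 5, 20)
        np.testing.assert_array_equal(
            labeled_abundance("pulse", tau, 3.0, 0.7),
            labeled_abundance("chase_unlabeled", tau, 3.0, 0.7),
        )

    def test_chase_clipped_at_zero(self):
        assert labeled_abundance("chase_labeled", 10.0, 5.0, 1.0, r0=0.5) == 0.0

    def test_exact_decay_switch(self):
        out = labeled_abundance("chase_labeled", 2.0, 9.9, 0.5, r0=4.0, exact_decay=True)
        assert out == pytest.approx(4.0 * np.exp(-1.0))

    def test_nonpositive_gamma_rejected(self):
        with pytest.raises(ValueError, match="gamma"):
            labeled_abundance("pulse", 1.0, 2.0, 0.0)


class TestNeighborhoods:
    def _dataset(self, expr, coords, kinds, taus):
        import pandas as pd

        from fatechain.datatypes import ExpressionDataset

        n = len(coords)
        meta = pd.DataFrame(
            {"experiment": kinds, "labeling_time": taus},
            index=[f"c{i}" for i in range(n)],
        )
        return ExpressionDataset(
            X=expr,
            cell_meta=meta,
            gene_ids=np.array(["g0"]),
            layers={"labeled": expr, "total": expr},
            embeddings={"pca": coords},
        )

    def test_no_zeros_returns_exactly_min_nonzero(self):
        coords = np.arange(6, dtype=float)[:, None]
        expr = np.ones((6, 1))
        ds = self._dataset(expr, coords, ["pulse"] * 6, [1.0] * 6)
        nb = select_labeling_neighborhoods(
            ds, "pca", LabelingDesign.from_cell_meta(ds.cell_meta), min_nonzero=3
        )
        np.testing.assert_array_equal(nb.neighbors(0, 0, ("pulse", 1.0)), [0, 1, 2])

    def test_interleaved_zeros_included_up_to_cut(self):
        # distances from cell 0: 0(self),1,2,3,4 — expression 1,0,5,0,7
        coords = np.arange(5, dtype=float)[:, None]
        expr = np.array([[1.0], [0.0], [5.0], [0.0], [7.0]])
        ds = self._dataset(expr, coords, ["pulse"] * 5, [1.0] * 5)
        nb = select_labeling_neighborhoods(
            ds, "pca", LabelingDesign.from_cell_meta(ds.cell_meta), min_nonzero=3
        )
        np.testing.assert_array_equal(
            nb.neighbors(0, 0, ("pulse", 1.0)), [0, 1, 2, 3, 4]
        )

    def test_min_nonzero_one_cuts_at_first_expressing_cell(self):
        coords = np.arange(4, dtype=float)[:, None]
        expr = np.array([[0.0], [0.0], [2.0], [2.0]])
        ds = self._dataset(expr, coords, ["pulse"] * 4, [1.0] * 4)
        nb = select_labeling_neighborhoods(
            ds, "pca", LabelingDesign.from_cell_meta(ds.cell_meta), min_nonzero=1
        )
        np.testing.assert_array_equal(nb.neighbors(0, 0, ("pulse", 1.0)), [0, 1, 2])

    def test_sparse_stratum_falls_back_to_whole_stratum(self):
        coords = np.arange(4, dtype=float)[:, None]
        expr = np.array([[1.0], [0.0], [0.0], [0.0]])
        ds = self._dataset(expr, coords, ["pulse"] * 4, [1.0] * 4)
        nb = select_labeling_neighborhoods(
            ds, "pca", LabelingDesign.from_cell_meta(ds.cell_meta), min_nonzero=3
        )
        out = nb.neighbors(0, 0, ("pulse", 1.0))
        assert len(out) == 4
        assert nb.n_fallbacks == 1


class TestFitRateCurve:
    def test_noiseless_pulse_round_trip(self):
        tau = np.tile([0.5, 1.0, 2.0], 4)
        y = labeled_abundance("pulse", tau, 2.0, 1.0)
        a, g, r0, loss = fit_rate_curve(y, tau, np.full(len(tau), "pulse", object))
        assert a == pytest.approx(2.0, rel=1e-3)
        assert g == pytest.approx(1.0, rel=1e-3)
        assert loss < 1e-10

    def test_noiseless_chase_round_trip(self):
        tau = np.tile([0.5, 1.0, 2.0], 4)
        y = labeled_abundance("chase_labeled", tau, 2.0, 1.0, r0=2.0)
        a, g, r0, _ = fit_rate_curve(y, tau, np.full(len(tau), "chase", object))
        assert (a, g, r0) == pytest.approx((2.0, 1.0, 2.0), rel=1e-3)

    def test_joint_pulse_and_chase(self):
        tau = np.array([0.5, 1, 2, 0.5, 1, 2])
        kind = np.array(["pulse"] * 3 + ["chase"] * 3, dtype=object)
        y = np.where(
            kind == "pulse",
            labeled_abundance("pulse", tau, 2.0, 1.0),
            labeled_abundance("chase_labeled", tau, 2.0, 1.0, r0=2.0),
        )
        a, g, r0, _ = fit_rate_curve(y, tau, kind)
        assert (a, g, r0) == pytest.approx((2.0, 1.0, 2.0), rel=1e-3)

    def test_single_pulse_duration_not_identifiable(self):
        tau = np.full(5, 1.0)
        y = labeled_abundance("pulse", tau, 2.0, 1.0)
        with pytest.raises(ValueError, match="2 distinct durations"):
            fit_rate_curve(y, tau, np.full(5, "pulse", object))

    def test_two_chase_durations_not_identifiable(self):
        tau = np.tile([0.5, 1.0], 3)
        y = labeled_abundance("chase_labeled", tau, 2.0, 1.0, r0=2.0)
        with pytest.raises(ValueError, match="3 distinct durations"):
            fit_rate_curve(y, tau, np.full(len(tau), "chase", object))

    def test_all_zero_observations_flagged_missing(self):
        tau = np.tile([0.5, 1.0], 2)
        out = fit_rate_curve(np.zeros(4), tau, np.full(4, "pulse", object))
        assert all(np.isnan(v) for v in out)

    def test_noisy_recovery_within_tolerance(self):
        rng = np.random.default_rng(0)
        errs = []
        for _ in range(30):
            a, g = rng.uniform(0.5, 5), rng.uniform(0.2, 2)
            tau = np.tile([0.5, 1.0, 2.0], 7)  # ~20-cell neighborhood
            y = labeled_abundance("pulse", tau, a, g)
            y = y * (1 + 0.05 * rng.normal(size=y.shape))
            ah, gh, _, _ = fit_rate_curve(y, tau, np.full(len(tau), "pulse", object))
            errs.append(max(abs(ah - a) / a, abs(gh - g) / g))
        assert np.median(errs) < 0.15


class TestFitKineticRates:
    def test_noiseless_dataset_recovers_planted_rates(self):
        ds, truth = simulate_pulse_chase(
            n_cells=300, n_genes=10, noise_model="none", seed=2, maturation_lag=0.0
        )
        rates = fit_kinetic_rates(ds, smooth=False)
        # genes with spatially constant rates are recovered essentially
        # exactly; genes whose α varies over the manifold are averaged over
        # the 20-cell neighborhoods, leaving a locality bias
        varying = set(truth.decay_genes.tolist())
        for genes in truth.driver_genes.values():
            varying |= set(genes.tolist())
        constant = np.array(sorted(set(range(ds.n_genes)) - varying))
        assert constant.size > 0
        rel_const = np.abs(rates.gamma[:, constant] - truth.gamma[:, constant])
        rel_const = rel_const / truth.gamma[:, constant]
        assert np.nanmax(rel_const) < 1e-4
        rel_all = np.abs(rates.gamma - truth.gamma) / truth.gamma
        assert np.nanmedian(rel_all) < 0.25

    def test_missing_entries_flagged_not_zero(self):
        ds, _ = simulate_pulse_chase(
            n_cells=40, n_genes=4, noise_model="none", seed=3
        )
        ds.layers["labeled"][:, 0] = 0.0
        rates = fit_kinetic_rates(ds, smooth=False)
        assert np.all(np.isnan(rates.gamma[:, 0]))
        assert rates.missing[:, 0].all()


class TestRatesToVelocity:
    def _rates(self, alpha, gamma):
        from fatechain.labeling import KineticRates

        a = np.asarray(alpha, dtype=float)
        g = np.asarray(gamma, dtype=float)
        return KineticRates(alpha=a, gamma=g, r0=np.zeros_like(a), fit_loss=np.zeros_like(a))

    def test_steady_state_velocity_is_zero(self):
        rates = self._rates([[2.0]], [[1.0]])
        V = rates_to_velocity(rates, np.array([[2.0]]))
        assert V.V[0, 0] == 0.0

    def test_arithmetic(self):
        rates = self._rates([[2.0]], [[1.0]])
        V = rates_to_velocity(rates, np.array([[0.5]]))
        assert V.V[0, 0] == pytest.approx(1.5)

    def test_missing_rate_propagates_to_missing_velocity(self):
        rates = self._rates([[np.nan]], [[np.nan]])
        V = rates_to_velocity(rates, np.array([[1.0]]))
        assert np.isnan(V.V[0, 0])


class TestLabelingDesign:
    def test_duration_preconditions(self):
        d = LabelingDesign(
            kind=np.array(["pulse", "pulse"], dtype=object), tau=np.array([1.0, 1.0])
        )
        with pytest.raises(ValueError, match="at least 2"):
            d.validate_durations()
        d = LabelingDesign(
            kind=np.array(["chase"] * 2, dtype=object), tau=np.array([1.0, 2.0])
        )
        with pytest.raises(ValueError, match="at least 3"):
            d.validate_durations()

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown experiment kinds"):
            LabelingDesign(kind=np.array(["wash"], dtype=object), tau=np.array([1.0]))
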