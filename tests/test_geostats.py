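import numpy as np
import pytest
from scipy.spatial.distance import cdist

from terraflux.geostats import (
    VariogramModel,
    VariogramRejection,
    empirical_variogram,
    fit_variogram_model,
    kriging_external_drift,
    loo_cross_validate,
    ordinary_kriging,
    select_model,
    simulate_field,
    study_diagonal,
)


def scatter_points(n, seed, size=100.0):
    rng = np.random.default_rng(seed)
    return rng.random((n, 2)) * size


# ------------------------------------------------------------ empirical
class TestEmpiricalVariogram:
    def test_constant_field_zero_semivariance(self):
        pos = scatter_points(15, 0)
        emp = empirical_variogram(pos, np.full(15, 3.0))
        np.testing.assert_allclose(emp.gamma, 0.0)

    def test_two_points_single_bin(self):
        emp = empirical_variogram(
            np.array([[0.0, 0.0], [1.0, 0.0]]), np.array([0.0, 2.0]), n_bins=1, max_lag=2.0
        )
        assert emp.gamma[0] == pytest.approx(2.0)  # (0-2)^2 / 2
        assert emp.counts[0] == 1

    def test_matches_brute_force_pair_loop(self):
        """Bin-by-bin equality with an O(n^2) double loop at n = 12."""
        pos = scatter_points(12, 1)
        vals = np.random.default_rng(2).normal(size=12)
        n_bins, max_lag = 5, 60.0
        emp = empirical_variogram(pos, vals, n_bins=n_bins, max_lag=max_lag)
        edges = np.linspace(0, max_lag, n_bins + 1)
        sums = np.zeros(n_bins)
        cnts = np.zeros(n_bins)
        lags = np.zeros(n_bins)
        for i in range(12):
            for j in range(i + 1, 12):
                h = np.hypot(*(pos[i] - pos[j]))
                if h > max_lag or h == 0:
                    continue
                b = min(int(np.searchsorted(edges[1:-1], h, side="right")), n_bins - 1)
                sums[b] += (vals[i] - vals[j]) ** 2
                cnts[b] += 1
                lags[b] += h
        keep = cnts > 0
        np.testing.assert_allclose(emp.gamma, sums[keep] / (2 * cnts[keep]))
        np.testing.assert_array_equal(emp.counts, cnts[keep])
        np.testing.assert_allclose(emp.lags, lags[keep] / cnts[keep])

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            empirical_variogram(np.zeros((5, 2)), np.arange(5.0))


# ---------------------------------------------------------------- fitting
class TestVariogramFit:
    def test_perfect_curve_recovered(self):
        truth = VariogramModel("spherical", 0.2, 1.0, 30.0)
        h = np.linspace(2, 60, 12)
        from terraflux.geostats import EmpiricalVariogram

        emp = EmpiricalVariogram(h, truth.gamma(h), np.full(12, 50), 60.0)
        fit = fit_variogram_model(emp, "spherical")
        assert fit.efficiency == pytest.approx(1.0, abs=1e-6)
        assert fit.sserr == pytest.approx(0.0, abs=1e-8)
        assert fit.range_ == pytest.approx(30.0, rel=1e-3)

    def test_pure_nugget_gives_zero_partial_sill(self):
        from terraflux.geostats import EmpiricalVariogram

        h = np.linspace(2, 60, 10)
        emp = EmpiricalVariogram(h, np.full(10, 0.8), np.full(10, 40), 60.0)
        for family in ("exponential", "gaussian", "spherical"):
            fit = fit_variogram_model(emp, family)
            assert fit.psill < 1e-4 * fit.nugget

    def test_spherical_field_recovery(self):
        """A simulated spherical-covariance field yields an E > 0.9 fit."""
        truth = VariogramModel("spherical", 0.0, 1.0, 30.0)
        pos = scatter_points(200, 3)
        vals = simulate_field(pos, truth, seed=4)
        emp = empirical_variogram(pos, vals)
        fit = fit_variogram_model(emp, "spherical")
        assert fit.efficiency > 0.9


class TestModelSelection:
    def mk(self, family, eff, rng_m=30.0, sserr=1.0):
        return VariogramModel(family, 0.1, 1.0, rng_m, sserr=sserr, efficiency=eff)

    def test_low_efficiency_discarded(self):
        keep = self.mk("spherical", 0.9)
        out = select_model([keep, self.mk("gaussian", 0.4)], diag=100.0)
        assert out is keep

    def test_all_rejected_gives_rejection_object(self):
        out = select_model([self.mk("spherical", 0.3), self.mk("gaussian", 0.4)], 100.0)
        assert isinstance(out, VariogramRejection)
        assert len(out.reasons) == 2

    def test_range_beyond_study_scale_discarded(self):
        out = select_model([self.mk("spherical", 0.9, rng_m=500.0)], diag=100.0)
        assert isinstance(out, VariogramRejection)

    def test_minimal_sserr_wins(self):
        a = self.mk("spherical", 0.9, sserr=1.0)
        b = self.mk("gaussian", 0.95, sserr=2.0)
        assert select_model([a, b], 100.0) is a

    def test_study_diagonal(self):
        pos = np.array([[0.0, 0.0], [80.0, 0.0], [0.0, 60.0]])
        assert study_diagonal(pos) == pytest.approx(100.0)


# ---------------------------------------------------------------- kriging
MODEL = VariogramModel("exponential", 0.0, 2.0, 40.0)


class TestOrdinaryKriging:
    def test_exact_at_data_points_zero_nugget(self):
        pos = scatter_points(8, 5)
        vals = np.random.default_rng(6).normal(size=8)
        pred, var = ordinary_kriging(pos, vals, MODEL, pos)
        np.testing.assert_allclose(pred, vals, atol=1e-8)
        np.testing.assert_allclose(var, 0.0, atol=1e-8)

    def test_constant_data_constant_prediction(self):
        pos = scatter_points(10, 7)
        targets = scatter_points(20, 8)
        pred, _ = ordinary_kriging(pos, np.full(10, 4.2), MODEL, targets)
        np.testing.assert_allclose(pred, 4.2, atol=1e-9)

    def test_shift_equivariance_implies_unit_weight_sum(self):
        pos = scatter_points(9, 9)
        vals = np.random.default_rng(10).normal(size=9)
        targets = scatter_points(15, 11)
        p0, _ = ordinary_kriging(pos, vals, MODEL, targets)
        p1, _ = ordinary_kriging(pos, vals + 100.0, MODEL, targets)
        np.testing.assert_allclose(p1 - p0, 100.0, atol=1e-9)

    def test_matches_dense_solve_oracle(self):
        """5-point OK equals a hand-assembled saturated linear system."""
        pos = scatter_points(5, 12)
        vals = np.random.default_rng(13).normal(size=5)
        targets = scatter_points(4, 14)
        pred, var = ordinary_kriging(pos, vals, MODEL, targets)
        gd = MODEL.gamma(cdist(pos, pos))
        for t in range(4):
            g0 = MODEL.gamma(cdist(pos, targets[t : t + 1])).ravel()
            a = np.zeros((6, 6))
            a[:5, :5] = gd
            a[5, :5] = a[:5, 5] = 1.0
            sol = np.linalg.solve(a, np.append(g0, 1.0))
            assert pred[t] == pytest.approx(sol[:5] @ vals, abs=1e-9)
            assert var[t] == pytest.approx(sol[:5] @ g0 + sol[5], abs=1e-9)

    def test_duplicate_points_named(self):
        pos = np.array([[0.0, 0.0], [1.0, 1.0], [1.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="duplicate"):
            ordinary_kriging(pos, np.arange(4.0), MODEL, pos[:1])


class TestKrigingExternalDrift:
    def test_pure_drift_limit(self):
        pos = scatter_points(10, 15)
        drift = np.random.default_rng(16).normal(size=10)
        vals = 2.0 * drift
        targets = scatter_points(12, 17)
        drift_t = np.random.default_rng(18).normal(size=12)
        pred, _ = kriging_external_drift(pos, vals, drift, MODEL, targets, drift_t)
        np.testing.assert_allclose(pred, 2.0 * drift_t, atol=1e-7)

    def test_constant_drift_equals_ok(self):
        pos = scatter_points(9, 19)
        vals = np.random.default_rng(20).normal(size=9)
        targets = scatter_points(10, 21)
        pred_ok, var_ok = ordinary_kriging(pos, vals, MODEL, targets)
        pred_ked, var_ked = kriging_external_drift(
            pos, vals, np.full(9, 7.0), MODEL, targets, np.full(10, 7.0)
        )
        np.testing.assert_allclose(pred_ked, pred_ok, atol=1e-8)
        np.testing.assert_allclose(var_ked, var_ok, atol=1e-8)

    def test_matches_dense_augmented_oracle(self):
        pos = scatter_points(6, 22)
        vals = np.random.default_rng(23).normal(size=6)
        drift = np.random.default_rng(24).normal(size=6)
        target = scatter_points(1, 25)
        drift_t = np.array([0.3])
        pred, var = kriging_external_drift(pos, vals, drift, MODEL, target, drift_t)
        gd = MODEL.gamma(cdist(pos, pos))
        g0 = MODEL.gamma(cdist(pos, target)).ravel()
        a = np.zeros((8, 8))
        a[:6, :6] = gd
        a[6, :6] = a[:6, 6] = 1.0
        a[7, :6] = a[:6, 7] = drift
        sol = np.linalg.solve(a, np.concatenate([g0, [1.0, drift_t[0]]]))
        assert pred[0] == pytest.approx(sol[:6] @ vals, abs=1e-9)
        assert var[0] == pytest.approx(sol[:6] @ g0 + sol[6] + sol[7] * drift_t[0], abs=1e-9)

    def test_variance_nonnegative_on_grid(self):
        from terraflux import ElevationRaster

        pos = scatter_points(12, 26, size=20.0)
        vals = np.random.default_rng(27).normal(size=12)
        drift = vals + np.random.default_rng(28).normal(size=12)
        grid = ElevationRaster(np.zeros((10, 10)), 2.0)
        dg = np.random.default_rng(29).normal(size=100)
        kmap = kriging_external_drift(pos, vals, drift, MODEL, grid, dg)
        assert (kmap.variance.values >= 0).all()


# ----------------------------------------------------------- cross-validation
class TestCrossValidation:
    def test_hand_computed_nrmse(self):
        pos = np.array([[0, 0], [10, 0], [0, 10], [10, 10], [5, 5], [2, 7]], float)
        vals = np.array([1.0, 2.0, 3.0, 4.0, 2.5, 3.1])
        report = loo_cross_validate(pos, vals, MODEL, "OK")
        preds = np.empty(6)
        for i in range(6):
            keep = np.arange(6) != i
            p, _ = ordinary_kriging(pos[keep], vals[keep], MODEL, pos[i : i + 1])
            preds[i] = p[0]
        err = preds - vals
        assert report.n_rmse == pytest.approx(np.sqrt(np.mean(err**2)) / 3.0)
        assert report.mean_err == pytest.approx(err.mean())

    def test_unbiased_on_structured_field(self):
        truth = VariogramModel("spherical", 0.05, 1.0, 40.0)
        pos = scatter_points(120, 30)
        vals = simulate_field(pos, truth, seed=31)
        report = loo_cross_validate(pos, vals, truth, "OK")
        assert abs(report.mean_err) < 0.05

    def test_msdr_near_one_for_well_specified_model(self):
        truth = VariogramModel("spherical", 0.1, 1.0, 30.0)
        pos = scatter_points(200, 32)
        vals = simulate_field(pos, truth, seed=33)
        report = loo_cross_validate(pos, vals, truth, "OK")
        assert report.msdr == pytest.approx(1.0, abs=0.3)

    def test_zero_span_rejected(self):
        pos = scatter_points(6, 34)
        with pytest.raises(ValueError):
            loo_cross_validate(pos, np.full(6, 1.0), MODEL, "OK")
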