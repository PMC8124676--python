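"""Ordinary kriging, masked grids, MKV, LOO cross-validation, selection."""

import numpy as np
import pytest

from soilkrige import (
    CrossValidationReport,
    Region,
    VariogramModel,
    krige_grid,
    krige_point,
    loo_cross_validate,
    select_model,
)
from conftest import scatter


def _dense_oracle(coords, values, model, x0):
    """Independently coded (n+1)x(n+1) augmented OK solve."""
    n = len(coords)
    A = np.zeros((n + 1, n + 1))
    for i in range(n):
        for j in range(n):
            h = float(np.hypot(*(coords[i] - coords[j])))
            A[i, j] = model.gamma(h)
        A[i, n] = 1.0
        A[n, i] = 1.0
    b = np.array([float(model.gamma(np.hypot(*(coords[i] - x0)))) for i in range(n)] + [1.0])
    sol = np.linalg.solve(A, b)
    pred = float(sol[:n] @ values)
    var = float(sol @ b)
    return sol[:n], sol[n], pred, var


class TestKrigePoint:
    def test_exact_at_sampled_point_zero_nugget(self):
        m = VariogramModel("spherical", 0.0, 1.0, 500.0)
        coords = np.array([[0.0, 0.0], [400.0, 0.0]])
        vals = np.array([7.0, 3.0])
        sol = krige_point(coords, vals, m, (0.0, 0.0))
        assert sol.weights[0] == pytest.approx(1.0, abs=1e-10)
        assert sol.prediction == pytest.approx(7.0, abs=1e-10)
        assert sol.variance == pytest.approx(0.0, abs=1e-10)

    def test_weights_sum_to_one(self, pb_model, rng):
        coords = scatter(25, 3000.0, seed=51)
        vals = rng.normal(3.5, 0.4, 25)
        for target in [(0.0, 0.0), (1500.0, 1500.0), (5000.0, 5000.0)]:
            sol = krige_point(coords, vals, pb_model, target)
            assert abs(sol.weights.sum() - 1.0) < 1e-10

    def test_matches_independent_dense_solve(self, pb_model, rng):
        coords = scatter(5, 2000.0, seed=52)
        vals = rng.normal(3.5, 0.4, 5)
        x0 = np.array([900.0, 1100.0])
        sol = krige_point(coords, vals, pb_model, x0)
        w, mu, pred, var = _dense_oracle(coords, vals, pb_model, x0)
        np.testing.assert_allclose(sol.weights, w, rtol=1e-9, atol=1e-12)
        assert sol.lagrange == pytest.approx(mu, rel=1e-9, abs=1e-12)
        assert sol.prediction == pytest.approx(pred, rel=1e-9)
        assert sol.variance == pytest.approx(var, rel=1e-9, abs=1e-12)

    def test_translation_equivariance_in_values(self, pb_model, rng):
        coords = scatter(12, 2000.0, seed=53)
        vals = rng.normal(size=12)
        a = krige_point(coords, vals, pb_model, (500.0, 500.0))
        b = krige_point(coords, vals + 11.0, pb_model, (500.0, 500.0))
        assert b.prediction == pytest.approx(a.prediction + 11.0, rel=1e-9)
        assert b.variance == pytest.approx(a.variance, rel=1e-12)

    def test_duplicate_points_rejected(self, pb_model):
        coords = np.array([[0.0, 0.0], [0.1, 0.0], [500.0, 0.0]])
        with pytest.raises(ValueError, match="duplicate"):
            krige_point(coords, np.ones(3), pb_model, (10.0, 10.0))

    def test_max_neighbors_restricts_system(self, pb_model, rng):
        coords = scatter(30, 3000.0, seed=54)
        vals = rng.normal(size=30)
        sol = krige_point(coords, vals, pb_model, (1500.0, 1500.0), max_neighbors=8)
        assert len(sol.weights) == 8


class TestKrigeGrid:
    def test_single_cell_at_sample_zero_nugget(self):
        m = VariogramModel("spherical", 0.0, 1.0, 500.0)
        region = Region.rectangle(0.0, 0.0, 100.0, 100.0)
        coords = np.array([[50.0, 50.0], [400.0, 50.0]])
        grid = krige_grid(coords, np.array([2.0, 5.0]), m, region, cell_size=100.0)
        assert grid.mask.sum() == 1
        assert grid.mkv == pytest.approx(0.0, abs=1e-10)

    def test_mkv_matches_pointwise_recomputation(self, pb_model, rng):
        region = Region.rectangle(0.0, 0.0, 1000.0, 1000.0)
        coords = scatter(15, 1000.0, seed=55)
        vals = rng.normal(size=15)
        grid = krige_grid(coords, vals, pb_model, region, cell_size=250.0)
        gx, gy = grid.cell_centers()
        vs = []
        for i in range(grid.n_rows):
            for j in range(grid.n_cols):
                if grid.mask[i, j]:
                    sol = krige_point(coords, vals, pb_model, (gx[i, j], gy[i, j]))
                    assert grid.variances[i, j] == pytest.approx(sol.variance, rel=1e-9, abs=1e-12)
                    vs.append(sol.variance)
        assert grid.mkv == pytest.approx(np.mean(vs), rel=1e-12)

    def test_mkv_invariant_under_value_permutation(self, pb_model, rng):
        region = Region.rectangle(0.0, 0.0, 2000.0, 2000.0)
        coords = scatter(20, 2000.0, seed=56)
        vals = rng.normal(size=20)
        a = krige_grid(coords, vals, pb_model, region, cell_size=400.0)
        b = krige_grid(coords, np.roll(vals, 7), pb_model, region, cell_size=400.0)
        assert a.mkv == b.mkv

    def test_doubling_density_never_raises_mkv(self, pb_model):
        region = Region.rectangle(0.0, 0.0, 3000.0, 3000.0)
        for seed in range(10):
            pts = scatter(60, 3000.0, seed=100 + seed)
            sparse, full = pts[:30], pts
            a = krige_grid(sparse, np.zeros(30), pb_model, region, cell_size=500.0)
            b = krige_grid(full, np.zeros(60), pb_model, region, cell_size=500.0)
            assert b.mkv <= a.mkv + 1e-12

    def test_disjoint_region_error(self, pb_model):
        region = Region.rectangle(10_000.0, 10_000.0, 11_000.0, 11_000.0)
        coords = np.array([[0.0, 0.0], [100.0, 100.0]])
        with pytest.raises(ValueError, match="overlap"):
            krige_grid(coords, np.zeros(2), pb_model, region)

    def test_nearest_neighbor_mode_close_to_global(self, pb_model, rng):
        region = Region.rectangle(0.0, 0.0, 3000.0, 3000.0)
        coords = scatter(40, 3000.0, seed=57)
        vals = rng.normal(size=40)
        a = krige_grid(coords, vals, pb_model, region, cell_size=500.0, max_neighbors=None)
        b = krige_grid(coords, vals, pb_model, region, cell_size=500.0, max_neighbors=30)
        assert np.nanmax(np.abs(a.predictions - b.predictions)) < 0.2
        assert abs(a.mkv - b.mkv) < 0.05 * a.mkv


class TestCrossValidation:
    def test_small_n_matches_manual_assembly(self, pb_model, rng):
        coords = scatter(4, 1500.0, seed=58)
        vals = rng.normal(3.5, 0.4, 4)
        rep = loo_cross_validate(coords, vals, pb_model)
        preds, sigmas = [], []
        for i in range(4):
            keep = [j for j in range(4) if j != i]
            sol = krige_point(coords[keep], vals[keep], pb_model, coords[i])
            preds.append(sol.prediction)
            sigmas.append(np.sqrt(sol.variance))
        resid = np.array(preds) - vals
        std = resid / np.array(sigmas)
        assert rep.me == pytest.approx(resid.mean(), rel=1e-12)
        assert rep.rmse == pytest.approx(np.sqrt((resid**2).mean()), rel=1e-12)
        assert rep.mse == pytest.approx(std.mean(), rel=1e-12)
        assert rep.ase == pytest.approx(np.mean(sigmas), rel=1e-12)
        assert rep.rmsse == pytest.approx(np.sqrt((std**2).mean()), rel=1e-12)

    def test_equal_sigmas_tie_rmsse_to_rmse_over_ase(self):
        # pure-nugget model: every LOO sigma identical, so rmsse = rmse/ase
        m = VariogramModel("spherical", nugget=0.3, partial_sill=1e-12, range_m=100.0)
        pts = np.array([[0.0, 0.0], [1000.0, 0.0], [0.0, 1000.0], [1000.0, 1000.0]])
        vals = np.array([1.0, 2.0, 4.0, 8.0])
        rep = loo_cross_validate(pts, vals, m)
        assert np.std([rep.ase]) == 0
        assert rep.rmsse == pytest.approx(rep.rmse / rep.ase, rel=1e-9)


def _rep(rmse, me=0.0, mse=0.0, rmsse=1.0):
    return CrossValidationReport(me=me, rmse=rmse, mse=mse, ase=rmse, rmsse=rmsse, n=10)


class TestSelectModel:
    def test_single_candidate(self):
        assert select_model([("spherical", _rep(1.0))]) == "spherical"

    def test_dominating_candidate_wins(self):
        cands = [
            ("spherical", _rep(1.0, me=0.01, mse=0.01, rmsse=1.01)),
            ("gaussian", _rep(2.0, me=0.5, mse=0.2, rmsse=1.4)),
            ("exponential", _rep(1.5, me=0.3, mse=0.1, rmsse=0.7)),
        ]
        assert select_model(cands) == "spherical"

    def test_conflicting_ranks_match_enumeration(self):
        from scipy.stats import rankdata

        cands = [
            ("spherical", _rep(1.0, me=0.9, mse=0.05, rmsse=1.30)),
            ("gaussian", _rep(1.2, me=0.1, mse=0.50, rmsse=1.05)),
            ("exponential", _rep(1.4, me=0.4, mse=0.02, rmsse=0.99)),
        ]
        mat = np.array([
            [r.rmse for _, r in cands],
            [abs(r.me) for _, r in cands],
            [abs(r.mse) for _, r in cands],
            [abs(r.rmsse - 1) for _, r in cands],
        ])
        sums = sum(rankdata(row) for row in mat)
        expected = cands[int(np.argmin(sums))][0]
        assert select_model(cands) == expected

    def test_empty_error(self):
        with pytest.raises(ValueError):
            select_model([])
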