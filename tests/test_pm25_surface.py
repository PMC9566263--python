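import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from aerequity import pm25_surface as ps

COV = list(ps.COVARIATES)


def _station_frame(rng, n=10, y=None):
    df = pd.DataFrame(
        {
            "x": rng.uniform(0, 20_000, n),
            "y": rng.uniform(0, 20_000, n),
            "aod": rng.uniform(0.2, 0.9, n),
            "pop": rng.uniform(0.5, 3.0, n),
            "ndvi": rng.uniform(-0.2, 0.8, n),
            "road": rng.uniform(0.5, 2.0, n),
            "np_dist": rng.uniform(0.1, 3.0, n),
        }
    )
    df["pm25"] = rng.uniform(40, 120, n) if y is None else y
    return df


class TestGWR:
    def test_constant_response_gives_constant_intercept(self, rng):
        st = _station_frame(rng, 12)
        st["pm25"] = 55.0
        fit = ps.fit_gwr(st, bandwidth=5000.0)
        np.testing.assert_allclose(fit.coefficients[:, 0], 55.0, atol=1e-6)
        np.testing.assert_allclose(fit.coefficients[:, 1:], 0.0, atol=1e-6)

    def test_infinite_bandwidth_equals_ols(self, rng):
        st = _station_frame(rng, 10)
        fit = ps.fit_gwr(st, bandwidth=1e9)
        X = np.column_stack([np.ones(len(st))] + [st[c].to_numpy() for c in COV])
        y = st["pm25"].to_numpy()
        # independent normal-equations oracle
        beta_ols = np.linalg.solve(X.T @ X, X.T @ y)
        for i in range(len(st)):
            np.testing.assert_allclose(fit.coefficients[i], beta_ols, atol=1e-8)

    def test_fitted_plus_residual_reconstructs_observations(self, rng):
        st = _station_frame(rng, 15)
        fit = ps.fit_gwr(st, bandwidth=4000.0)
        np.testing.assert_allclose(
            fit.fitted + fit.residuals, st["pm25"].to_numpy(), atol=1e-9
        )
        assert fit.r2 <= 1.0

    def test_too_few_stations_raises(self, rng):
        with pytest.raises(ValueError, match="at least"):
            ps.fit_gwr(_station_frame(rng, 5))

    def test_duplicate_coordinates_raise(self, rng):
        st = _station_frame(rng, 10)
        st.loc[1, ["x", "y"]] = st.loc[0, ["x", "y"]].to_numpy()
        with pytest.raises(ValueError, match="duplicate"):
            ps.fit_gwr(st, bandwidth=5000.0)


class TestPredictGrid:
    def test_colocated_cell_reproduces_exact_fit(self, rng):
        st = _station_frame(rng, 10)
        # exact linear response: zero-residual fit at any bandwidth
        beta = np.array([10.0, 20.0, 1.5, -8.0, 2.0, -1.0])
        X = np.column_stack([np.ones(len(st))] + [st[c].to_numpy() for c in COV])
        st["pm25"] = X @ beta
        fit = ps.fit_gwr(st, bandwidth=1e9)
        grid = st.drop(columns="pm25").copy()
        grid["cell_id"] = np.arange(len(grid))
        surf = ps.predict_grid(fit, grid)
        np.testing.assert_allclose(surf.values, X @ beta, rtol=1e-8)

    def test_zero_covariates_predict_local_intercept(self, rng):
        st = _station_frame(rng, 10)
        fit = ps.fit_gwr(st, bandwidth=5000.0)
        grid = pd.DataFrame(
            {"x": [5000.0], "y": [5000.0], **{c: [0.0] for c in COV}}
        )
        surf = ps.predict_grid(fit, grid)
        d = np.hypot(fit.x[:, 0] - 5000, fit.x[:, 1] - 5000)
        w = 1 / d**2
        expected = float(w @ fit.coefficients[:, 0] / w.sum())
        assert surf.values[0] == pytest.approx(max(expected, 0.0))

    def test_hand_set_coefficient_dot_product(self):
        fit = ps.GWRFit(
            x=np.array([[0.0, 0.0]]),
            coefficients=np.array([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]]),
            fitted=np.zeros(1),
            residuals=np.zeros(1),
            bandwidth=1.0,
            kernel_name="gaussian",
            r2=1.0,
        )
        grid = pd.DataFrame(
            {
                "x": [10.0, 20.0, 30.0],
                "y": [0.0, 0.0, 0.0],
                "aod": [1.0, 0.0, 2.0],
                "pop": [0.0, 1.0, 1.0],
                "ndvi": [0.0, 0.0, 1.0],
                "road": [0.0, 1.0, 0.0],
                "np_dist": [1.0, 0.0, 0.0],
            }
        )
        surf = ps.predict_grid(fit, grid)
        np.testing.assert_allclose(surf.values, [1 + 2 + 6, 1 + 3 + 5, 1 + 4 + 3 + 4])

    def test_missing_covariate_column_raises(self, rng):
        st = _station_frame(rng, 10)
        fit = ps.fit_gwr(st, bandwidth=5000.0)
        with pytest.raises(ValueError, match="missing covariate"):
            ps.predict_grid(fit, st[["x", "y", "aod"]])


class TestVariogram:
    def test_constant_field_pure_nugget(self, rng):
        pts = rng.uniform(0, 1000, (20, 2))
        vm = ps.fit_variogram(pts, np.full(20, 7.0))
        assert vm.sill == 0.0 and vm.nugget == 0.0

    def test_recovers_known_exponential_range(self):
        rng = np.random.default_rng(77)
        n, true_range, sigma2 = 400, 2000.0, 4.0
        pts = rng.uniform(0, 10_000, (n, 2))
        from scipy.spatial.distance import cdist

        C = sigma2 * np.exp(-3.0 * cdist(pts, pts) / true_range)
        z = np.linalg.cholesky(C + 1e-10 * np.eye(n)) @ rng.standard_normal(n)
        vm = ps.fit_variogram(pts, z, n_bins=15, max_lag_m=5000.0)
        assert true_range / 2 < vm.range_m < true_range * 2

    def test_max_lag_below_min_distance_raises(self):
        pts = np.array([[0, 0], [1000, 0], [0, 1000], [1000, 1000]] * 3, dtype=float)
        pts += np.arange(12)[:, None]  # avoid exact duplicates
        with pytest.raises(ValueError, match="no pairs"):
            ps.empirical_variogram(pts, np.arange(12.0), max_lag_m=1.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ps.VariogramModel("exponential", nugget=2.0, sill=1.0, range_m=100.0)


class TestKriging:
    def test_exact_at_data_points_zero_nugget(self, rng):
        pts = rng.uniform(0, 5000, (15, 2))
        vals = rng.uniform(10, 50, 15)
        vm = ps.VariogramModel("exponential", 0.0, 25.0, 1500.0)
        surf = ps.krige(pts, vals, vm, pts)
        np.testing.assert_allclose(surf.values, vals, atol=1e-8)

    def test_constant_data_constant_prediction(self, rng):
        pts = rng.uniform(0, 5000, (12, 2))
        vm = ps.VariogramModel("spherical", 0.0, 9.0, 2000.0)
        tgt = rng.uniform(0, 5000, (30, 2))
        surf = ps.krige(pts, np.full(12, 42.0), vm, tgt)
        np.testing.assert_allclose(surf.values, 42.0, atol=1e-9)

    def test_two_point_system_against_hand_solution(self):
        vm = ps.VariogramModel("exponential", 0.0, 10.0, 1000.0)
        pts = np.array([[0.0, 0.0], [1000.0, 0.0]])
        vals = np.array([10.0, 20.0])
        # symmetric target: equal weights by the hand-solved 3x3 system
        surf = ps.krige(pts, vals, vm, np.array([[500.0, 0.0]]))
        assert surf.values[0] == pytest.approx(15.0, abs=1e-10)
        # asymmetric target: solve the Lagrange system independently
        tgt = np.array([[250.0, 0.0]])
        g01 = vm(np.array([1000.0]))[0]
        g0t = vm(np.array([250.0]))[0]
        g1t = vm(np.array([750.0]))[0]
        A = np.array([[0.0, g01, 1.0], [g01, 0.0, 1.0], [1.0, 1.0, 0.0]])
        w = np.linalg.solve(A, np.array([g0t, g1t, 1.0]))
        expected = w[0] * 10.0 + w[1] * 20.0
        surf = ps.krige(pts, vals, vm, tgt)
        assert surf.values[0] == pytest.approx(expected, abs=1e-10)

    def test_duplicate_points_deduplicated_to_mean(self):
        vm = ps.VariogramModel("exponential", 0.0, 10.0, 1000.0)
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [1000.0, 0.0]])
        vals = np.array([10.0, 30.0, 20.0])
        surf = ps.krige(pts, vals, vm, np.array([[0.0, 0.0]]))
        assert surf.values[0] == pytest.approx(20.0)  # mean of 10 and 30


class TestBlockAverage:
    def _surface(self, values, cells):
        xs = np.array([c.centroid.x for c in cells])
        ys = np.array([c.centroid.y for c in cells])
        return ps.ConcentrationSurface(xs, ys, np.asarray(values, float), "kriged")

    def test_uniform_surface(self):
        cells = [box(i, 0, i + 1, 1) for i in range(4)]
        blocks = pd.DataFrame({"block_id": [0], "geometry": [box(0, 0, 4, 1)]})
        out = ps.block_average(self._surface([7, 7, 7, 7], cells), blocks, cells)
        assert out.loc[0] == pytest.approx(7.0)

    def test_equal_overlap_two_cells(self):
        cells = [box(0, 0, 1, 1), box(1, 0, 2, 1)]
        blocks = pd.DataFrame({"block_id": ["b"], "geometry": [box(0.5, 0, 1.5, 1)]})
        out = ps.block_average(self._surface([10, 20], cells), blocks, cells)
        assert out.loc["b"] == pytest.approx(15.0)

    def test_block_means_within_cell_range(self, rng):
        cells = [box(i, j, i + 1, j + 1) for i in range(4) for j in range(4)]
        vals = rng.uniform(0, 100, 16)
        blocks = pd.DataFrame(
            {"block_id": [0, 1], "geometry": [box(0, 0, 2, 4), box(2, 0, 4, 4)]}
        )
        out = ps.block_average(self._surface(vals, cells), blocks, cells)
        assert out.min() >= vals.min() and out.max() <= vals.max()

    def test_empty_block_nearest_cell_fallback(self):
        cells = [box(0, 0, 1, 1)]
        blocks = pd.DataFrame({"block_id": ["far"], "geometry": [box(5, 5, 6, 6)]})
        out = ps.block_average(self._surface([33.0], cells), blocks, cells)
        assert out.loc["far"] == pytest.approx(33.0)
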