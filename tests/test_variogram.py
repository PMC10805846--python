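"""Geostatistics: detrending, directional semivariograms, exponential fits."""

import numpy as np
import pytest

import understory as u
from understory.grids import Grid, Raster, haversine_km, initial_bearing_deg
from understory.variogram import (detrend_surface, empirical_semivariogram,
                                  fit_exponential, compare_heterogeneity,
                                  raster_to_points, coarsen_mean, Semivariogram)


def brute_force_semivariogram(lats, lons, values, direction, tolerance, max_lag, bin_width):
    """Independent all-pairs double-loop oracle."""
    edges = np.arange(0.0, max_lag + bin_width, bin_width)
    nbins = len(edges) - 1
    sums = np.zeros(nbins)
    counts = np.zeros(nbins, dtype=int)
    n = len(values)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(haversine_km(lats[i], lons[i], lats[j], lons[j]))
            if d <= 0 or d > max_lag:
                continue
            b = float(initial_bearing_deg(lats[i], lons[i], lats[j], lons[j]))
            ang = abs((b - direction + 90.0) % 180.0 - 90.0)
            if ang > tolerance:
                continue
            k = min(int(d // bin_width), nbins - 1)
            sums[k] += 0.5 * (values[i] - values[j]) ** 2
            counts[k] += 1
    keep = counts > 0
    centres = (edges[:-1] + edges[1:]) / 2
    return centres[keep], sums[keep] / counts[keep], counts[keep]


class TestDetrend:
    def test_exact_plane_zero_residuals(self):
        rng = np.random.default_rng(0)
        lats, lons = rng.uniform(-2, 0, 50), rng.uniform(20, 22, 50)
        vals = 3.0 + 0.5 * lats - 0.2 * lons
        res, betas = detrend_surface(lats, lons, vals)
        np.testing.assert_allclose(res, 0.0, atol=1e-10)
        np.testing.assert_allclose(betas, [3.0, 0.5, -0.2], atol=1e-10)

    def test_residual_orthogonality(self):
        rng = np.random.default_rng(1)
        lats, lons = rng.uniform(-2, 0, 80), rng.uniform(20, 22, 80)
        vals = rng.normal(25, 2, 80)
        res, _ = detrend_surface(lats, lons, vals)
        assert abs(res.mean()) < 1e-10
        assert abs(res @ lats) < 1e-7 and abs(res @ lons) < 1e-7

    def test_collinear_points_rejected(self):
        lats = np.linspace(-1, 0, 10)
        lons = 2 * lats + 20
        with pytest.raises(ValueError):
            detrend_surface(lats, lons, np.ones(10))

    def test_plane_plus_field_variance_recovered(self):
        grid = Grid(60, 60, -1.0, 20.0, 0.01)
        field = u.generate_grf(grid, 0.5, 5.0, seed=4)
        lat2d, lon2d = grid.center_mesh()
        vals = 10.0 - 3.0 * lat2d + 1.0 * lon2d + field
        res, _ = detrend_surface(lat2d.ravel(), lon2d.ravel(), vals.ravel())
        # OLS is linear: adding an exact plane leaves the residuals unchanged
        res_field, _ = detrend_surface(lat2d.ravel(), lon2d.ravel(), field.ravel())
        np.testing.assert_allclose(res, res_field, atol=1e-8)
        # and the residual variance reflects the field's (minus its incidental trend)
        assert res.var() == pytest.approx(field.var(), rel=0.25)


class TestEmpiricalSemivariogram:
    def test_two_point_example(self):
        # values 1 and 3: gamma = 0.5 * (1-3)^2 = 2
        sv = empirical_semivariogram(np.array([0.0, 0.0]), np.array([20.0, 20.2]),
                                     np.array([1.0, 3.0]), direction=90.0,
                                     tolerance=90.0, max_lag=50.0, bin_width=25.0)
        assert len(sv.gamma) == 1
        assert sv.gamma[0] == 2.0

    def test_constant_field_zero_everywhere(self):
        rng = np.random.default_rng(2)
        lats, lons = rng.uniform(-1, 0, 40), rng.uniform(20, 21, 40)
        sv = empirical_semivariogram(lats, lons, np.full(40, 5.0),
                                     tolerance=90.0, max_lag=120.0)
        assert np.all(sv.gamma == 0.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        n = 150
        lats, lons = rng.uniform(-2, 0, n), rng.uniform(20, 22, n)
        vals = rng.normal(0, 1, n)
        for direction, tol in [(90.0, 22.5), (0.0, 45.0), (135.0, 10.0)]:
            sv = empirical_semivariogram(lats, lons, vals, direction=direction,
                                         tolerance=tol, max_lag=200.0, bin_width=20.0)
            lag_o, gamma_o, n_o = brute_force_semivariogram(
                lats, lons, vals, direction, tol, 200.0, 20.0)
            np.testing.assert_allclose(sv.lag_km, lag_o)
            np.testing.assert_allclose(sv.gamma, gamma_o, rtol=1e-12)
            np.testing.assert_array_equal(sv.n_pairs, n_o)

    def test_direction_axis_symmetry(self):
        rng = np.random.default_rng(4)
        n = 100
        lats, lons = rng.uniform(-2, 0, n), rng.uniform(20, 22, n)
        vals = rng.normal(0, 1, n)
        a = empirical_semivariogram(lats, lons, vals, direction=30.0, max_lag=150.0)
        b = empirical_semivariogram(lats, lons, vals, direction=210.0, max_lag=150.0)
        np.testing.assert_allclose(a.gamma, b.gamma)

    def test_invariant_to_constant_shift(self):
        rng = np.random.default_rng(5)
        n = 80
        lats, lons = rng.uniform(-2, 0, n), rng.uniform(20, 22, n)
        vals = rng.normal(0, 1, n)
        a = empirical_semivariogram(lats, lons, vals, tolerance=90.0, max_lag=150.0)
        b = empirical_semivariogram(lats, lons, vals + 100.0, tolerance=90.0, max_lag=150.0)
        np.testing.assert_allclose(a.gamma, b.gamma, atol=1e-9)

    def test_max_lag_below_bin_rejected(self):
        with pytest.raises(ValueError):
            empirical_semivariogram(np.zeros(3), np.arange(3.0) + 20, np.ones(3),
                                    max_lag=5.0, bin_width=10.0)


class TestExponentialFit:
    def test_recovers_noiseless_model_parameters(self):
        h = np.linspace(5, 300, 30)
        gamma = 0.0 + 1.0 * (1 - np.exp(-h / 50.0))
        sv = Semivariogram(lag_km=h, gamma=gamma, n_pairs=np.full(30, 100),
                           direction=90.0, tolerance=22.5, max_lag=300.0)
        fit = fit_exponential(sv)
        assert fit.nugget == pytest.approx(0.0, abs=1e-3)
        assert fit.partial_sill == pytest.approx(1.0, rel=0.01)
        assert fit.range_param == pytest.approx(50.0, rel=0.01)
        assert fit.minimum_distance == pytest.approx(50.0 * np.log(20), rel=0.01)

    def test_pure_nugget_has_no_practical_range(self):
        h = np.linspace(5, 300, 20)
        sv = Semivariogram(lag_km=h, gamma=np.full(20, 0.8), n_pairs=np.full(20, 50),
                           direction=90.0, tolerance=22.5, max_lag=300.0)
        fit = fit_exponential(sv)
        assert fit.minimum_distance is None
        assert fit.sill == pytest.approx(0.8, rel=0.05)

    def test_too_few_bins_rejected(self):
        sv = Semivariogram(lag_km=np.array([10.0, 20.0]), gamma=np.array([1.0, 2.0]),
                           n_pairs=np.array([5, 5]), direction=90.0,
                           tolerance=22.5, max_lag=40.0)
        with pytest.raises(Exception):
            fit_exponential(sv)

    def test_grf_sill_and_range_recovery(self):
        # end-to-end: simulate fields of known structure, fit, compare
        grid = Grid(100, 100, -1.0, 20.0, 0.01)  # 111 km block
        truth_sill, truth_a = 1.0, 8.0
        sills, ds = [], []
        rng = np.random.default_rng(6)
        for s in range(20):
            f = u.generate_grf(grid, truth_sill, truth_a, seed=300 + s)
            lat2d, lon2d = grid.center_mesh()
            idx = rng.choice(f.size, 1000, replace=False)
            la, lo = lat2d.ravel()[idx], lon2d.ravel()[idx]
            z, _ = detrend_surface(la, lo, f.ravel()[idx])  # the standard workflow
            sv = empirical_semivariogram(la, lo, z, direction=90.0, tolerance=90.0,
                                         max_lag=60.0, bin_width=4.0)
            fit = fit_exponential(sv)
            sills.append(fit.sill)
            ds.append(fit.minimum_distance)
        assert np.mean(sills) == pytest.approx(truth_sill, rel=0.25)
        assert np.mean(ds) == pytest.approx(truth_a * np.log(20), rel=0.25)


class TestCompareHeterogeneity:
    def _surface(self, grid, seed, fine=False):
        lat2d, lon2d = grid.center_mesh()
        base = 28.0 - 1.5 * lat2d + u.generate_grf(grid, 1.0, 30.0, seed)
        if fine:
            base = base + u.generate_grf(grid, 0.5, 5.0, seed + 5000)
        return Raster(grid, base)

    def test_identical_surfaces_identical_fits(self):
        grid = Grid(50, 50, -1.0, 20.0, 0.02)
        s = self._surface(grid, 7)
        comp = compare_heterogeneity(s, s, tolerance=90.0, max_lag=80.0, bin_width=8.0)
        assert comp.fit_under.sill == comp.fit_open.sill
        assert comp.d_ratio == pytest.approx(1.0)

    def test_fine_scale_structure_lowers_practical_range(self):
        grid = Grid(60, 60, -1.0, 20.0, 0.02)  # 133 km block
        wins = 0
        for s in range(10):
            t_open = self._surface(grid, 800 + s)
            t_under = Raster(grid, t_open.values + u.generate_grf(grid, 1.0, 4.0, 900 + s))
            comp = compare_heterogeneity(t_under, t_open, tolerance=90.0,
                                         max_lag=100.0, bin_width=8.0)
            if (comp.fit_under.minimum_distance is not None
                    and comp.fit_open.minimum_distance is not None
                    and comp.fit_under.minimum_distance < comp.fit_open.minimum_distance):
                wins += 1
        assert wins >= 8

    def test_coarsen_mean_blocks(self):
        grid = Grid(4, 4, 0.0, 0.0, 0.1)
        vals = np.arange(16.0).reshape(4, 4)
        out = coarsen_mean(Raster(grid, vals), 2)
        np.testing.assert_allclose(out.values,
                                   [[vals[:2, :2].mean(), vals[:2, 2:].mean()],
                                    [vals[2:, :2].mean(), vals[2:, 2:].mean()]])
        assert out.grid.cell_size == pytest.approx(0.2)
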