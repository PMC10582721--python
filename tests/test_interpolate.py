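"""Circle tiling, per-circle OLS and IDW blending."""

import numpy as np
import pandas as pd
import pytest

from phenomap import (
    ElevationGrid,
    InterpolationConfig,
    OnsetEstimate,
    fit_circle_models,
    idw_interpolate,
    interpolate,
    make_circle_grid,
    predict_at_points,
)
from phenomap.interpolate import CircleModel

GERMANY = (47.27, 55.06, 5.87, 15.04)


def plane_stations(n, seed=0, coef=(100.0, 0.03, -1.2, 2.5), extent=GERMANY, noise=0.0):
    rng = np.random.default_rng(seed)
    lat_min, lat_max, lon_min, lon_max = extent
    lats = rng.uniform(lat_min, lat_max, n)
    lons = rng.uniform(lon_min, lon_max, n)
    elevs = rng.uniform(0, 900, n)
    doy = coef[0] + coef[1] * elevs + coef[2] * lons + coef[3] * lats + noise * rng.normal(size=n)
    stations = pd.DataFrame(
        {"station_id": [f"S{i}" for i in range(n)], "lat": lats, "lon": lons, "elev_m": elevs}
    )
    onsets = [
        OnsetEstimate(station_id=f"S{i}", q=0.2, doy_hat=float(doy[i]), n=35) for i in range(n)
    ]
    return onsets, stations


class TestCircleGrid:
    def test_national_extent_yields_30_circles(self):
        grid = make_circle_grid(GERMANY, spacing_deg=1.95, radius_deg=1.95)
        assert grid.n_circles == 30
        assert grid.shape == (5, 6)

    def test_point_extent_yields_one_circle(self):
        grid = make_circle_grid((48.0, 48.0, 9.0, 9.0))
        assert grid.n_circles == 1

    def test_exact_span_of_one_spacing_yields_two_centers_per_axis(self):
        grid = make_circle_grid((48.0, 49.95, 9.0, 10.95), spacing_deg=1.95)
        assert grid.n_circles == 4
        assert grid.shape == (2, 2)

    def test_lattice_is_regular_and_anchored_at_minimum(self):
        grid = make_circle_grid(GERMANY)
        lats = np.unique(grid.center_lats)
        lons = np.unique(grid.center_lons)
        assert lats[0] == pytest.approx(GERMANY[0])
        assert lons[0] == pytest.approx(GERMANY[2])
        np.testing.assert_allclose(np.diff(lats), 1.95)
        np.testing.assert_allclose(np.diff(lons), 1.95)

    def test_coverage_every_point_near_some_center(self):
        grid = make_circle_grid(GERMANY)
        rng = np.random.default_rng(0)
        lats = rng.uniform(GERMANY[0], GERMANY[1], 200)
        lons = rng.uniform(GERMANY[2], GERMANY[3], 200)
        d = np.sqrt(
            (lats[:, None] - grid.center_lats[None, :]) ** 2
            + (lons[:, None] - grid.center_lons[None, :]) ** 2
        )
        assert (d.min(axis=1) <= grid.radius_deg).all()

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            make_circle_grid((49.0, 48.0, 9.0, 10.0))
        with pytest.raises(ValueError):
            make_circle_grid(GERMANY, spacing_deg=5.0, radius_deg=1.95)


class TestCircleModels:
    def test_exact_plane_recovered_in_every_valid_circle(self):
        onsets, stations = plane_stations(300, seed=1)
        grid = make_circle_grid(GERMANY)
        models = fit_circle_models(onsets, stations, grid)
        assert any(m.valid for m in models)
        for m in models:
            if m.valid:
                np.testing.assert_allclose(m.coef, [100.0, 0.03, -1.2, 2.5], rtol=1e-8)

    def test_undermanned_circle_flagged_invalid(self):
        onsets, stations = plane_stations(3, seed=2, extent=(48.0, 48.5, 9.0, 9.5))
        grid = make_circle_grid((48.0, 48.5, 9.0, 9.5))
        models = fit_circle_models(onsets, stations, grid, min_stations=4)
        assert all(not m.valid for m in models)

    def test_rank_deficient_design_flagged_invalid(self):
        # five stations on one point: lon/lat/elev columns are collinear
        stations = pd.DataFrame(
            {"station_id": [f"S{i}" for i in range(5)], "lat": 48.0, "lon": 9.0, "elev_m": 300.0}
        )
        onsets = [OnsetEstimate(station_id=f"S{i}", q=0.2, doy_hat=120.0, n=35) for i in range(5)]
        models = fit_circle_models(onsets, stations, make_circle_grid((48.0, 48.0, 9.0, 9.0)))
        assert all(not m.valid for m in models)

    def test_coefficients_match_normal_equations_oracle(self):
        """Five-station system solved independently via the normal equations."""
        stations = pd.DataFrame(
            {
                "station_id": ["S0", "S1", "S2", "S3", "S4"],
                "lat": [48.1, 48.9, 48.4, 48.7, 48.2],
                "lon": [9.1, 9.8, 9.3, 9.6, 9.9],
                "elev_m": [210.0, 540.0, 330.0, 460.0, 120.0],
            }
        )
        doys = [112.0, 131.0, 119.0, 127.0, 109.0]
        onsets = [
            OnsetEstimate(station_id=s, q=0.2, doy_hat=d, n=35)
            for s, d in zip(stations.station_id, doys)
        ]
        model = fit_circle_models(onsets, stations, make_circle_grid((48.5, 48.5, 9.5, 9.5)))[0]
        X = np.column_stack(
            [np.ones(5), stations.elev_m, stations.lon, stations.lat]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ np.array(doys))
        np.testing.assert_allclose(model.coef, beta, rtol=1e-8)


def uniform_models(coefs_list, centers):
    return [
        CircleModel(center_lat=c[0], center_lon=c[1], a0=co[0], a1=co[1], a2=co[2], a3=co[3],
                    n_stations=10, valid=True)
        for co, c in zip(coefs_list, centers)
    ]


class TestIdw:
    def grid(self):
        return ElevationGrid(xll=9.0, yll=48.0, cellsize=0.25, values=np.full((8, 8), 400.0))

    def test_identical_circles_reproduce_the_plane_exactly(self):
        coef = (100.0, 0.03, -1.2, 2.5)
        models = uniform_models([coef] * 4, [(48.0, 9.0), (48.0, 11.0), (50.0, 9.0), (50.0, 11.0)])
        pheno = idw_interpolate(models, self.grid())
        lat_g, lon_g = self.grid().cell_centers()
        expected = coef[0] + coef[1] * 400.0 + coef[2] * lon_g + coef[3] * lat_g
        np.testing.assert_allclose(pheno.values, expected, rtol=1e-12)

    def test_point_at_center_takes_that_circles_prediction(self):
        models = uniform_models([(100, 0, 0, 0), (200, 0, 0, 0)], [(48.5, 9.5), (49.5, 10.5)])
        val = predict_at_points(models, [48.5], [9.5], [0.0])
        assert val[0] == pytest.approx(100.0, abs=1e-9)

    def test_equidistant_cell_is_arithmetic_mean_with_power_2(self):
        models = uniform_models([(100, 0, 0, 0), (200, 0, 0, 0)], [(48.0, 9.0), (50.0, 9.0)])
        val = predict_at_points(models, [49.0], [9.0], [0.0])
        assert val[0] == pytest.approx(150.0)

    def test_blend_bounded_by_surrounding_predictions(self):
        rng = np.random.default_rng(5)
        centers = [(48.0, 9.0), (48.0, 11.0), (50.0, 9.0), (50.0, 11.0)]
        coefs = [tuple(rng.uniform(-1, 1, 4) + (120, 0, 0, 0)) for _ in centers]
        models = uniform_models(coefs, centers)
        g = self.grid()
        pheno = idw_interpolate(models, g)
        lat_g, lon_g = g.cell_centers()
        preds = np.stack(
            [m.a0 + m.a1 * 400.0 + m.a2 * lon_g + m.a3 * lat_g for m in models]
        )
        assert (pheno.values >= preds.min(axis=0) - 1e-9).all()
        assert (pheno.values <= preds.max(axis=0) + 1e-9).all()

    def test_cells_above_1000m_masked(self):
        vals = np.full((8, 8), 400.0)
        vals[0, :3] = 1400.0
        vals[1, 0] = 1000.0  # exactly at the threshold stays unmasked
        g = ElevationGrid(xll=9.0, yll=48.0, cellsize=0.25, values=vals)
        models = uniform_models([(100, 0, 0, 0)], [(49.0, 10.0)])
        pheno = idw_interpolate(models, g)
        assert pheno.mask.sum() == 3
        assert not pheno.mask[1, 0]
        assert np.isnan(pheno.values[0, 0])

    def test_mask_counts_conserved_with_nodata(self):
        vals = np.full((6, 6), 500.0)
        vals[2, 2] = np.nan
        vals[3:, 5] = 1500.0
        g = ElevationGrid(xll=9.0, yll=48.0, cellsize=0.25, values=vals)
        models = uniform_models([(100, 0, 0, 0)], [(48.5, 9.5)])
        pheno = idw_interpolate(models, g)
        assert pheno.mask.sum() == 1 + 3

    def test_cell_far_from_all_circles_falls_back_to_nearest(self):
        models = uniform_models([(100, 0, 0, 0), (200, 0, 0, 0)], [(48.0, 9.0), (70.0, 9.0)])
        cfg = InterpolationConfig(neighborhood_factor=0.5, radius_deg=0.5)
        val = predict_at_points(models, [55.0], [9.0], [0.0], cfg)
        assert val[0] == pytest.approx(100.0)

    def test_no_valid_circle_raises(self):
        with pytest.raises(ValueError, match="valid circle"):
            predict_at_points([CircleModel(48.0, 9.0)], [48.0], [9.0], [100.0])


class TestEndToEnd:
    def test_noisefree_plane_recovery_full_chain(self):
        onsets, stations = plane_stations(250, seed=3)
        rng = np.random.default_rng(0)
        dem = ElevationGrid(
            xll=GERMANY[2], yll=GERMANY[0], cellsize=0.5,
            values=rng.uniform(0, 900, (16, 19)),
        )
        pheno = interpolate(onsets, stations, dem, extent=GERMANY)
        lat_g, lon_g = dem.cell_centers()
        truth = 100.0 + 0.03 * dem.values - 1.2 * lon_g + 2.5 * lat_g
        np.testing.assert_allclose(pheno.values[~pheno.mask], truth[~pheno.mask], atol=1e-6)

    def test_station_order_does_not_change_the_map(self):
        onsets, stations = plane_stations(120, seed=4, noise=5.0)
        dem = ElevationGrid(xll=GERMANY[2], yll=GERMANY[0], cellsize=0.5,
                            values=np.full((16, 19), 350.0))
        a = interpolate(onsets, stations, dem, extent=GERMANY)
        perm = np.random.default_rng(1).permutation(len(onsets))
        b = interpolate([onsets[i] for i in perm], stations, dem, extent=GERMANY)
        np.testing.assert_array_equal(a.values, b.values)
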