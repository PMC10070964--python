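"""LST scaling, outlier filtering, reconstruction and compositing."""

import datetime as dt

import numpy as np
import pytest

from envgrid.grids import GridSpec, RasterLayer
from envgrid.lst import (
    LstAcquisition,
    composite_8day,
    eight_day_windows,
    filter_distribution,
    filter_lapse_outliers,
    fit_lapse_model,
    process_local_day,
    reconstruct_gaps,
    scale_lst,
)


@pytest.fixture
def linear_scene(dem):
    """Noiseless LST exactly linear in elevation: 30 - 0.0065*elev."""
    vals = 30.0 - 0.0065 * dem.values
    return RasterLayer(grid=dem.grid, values=vals,
                       nodata_mask=np.zeros(dem.grid.shape, bool), variable="LST")


class TestScaleLst:
    def test_freezing_point_dn(self, small_grid, make_layer):
        out = scale_lst(make_layer(small_grid, np.full((8, 8), 273.15 / 0.02)))
        assert np.allclose(out.values, 0.0)

    def test_worked_dn_example(self, small_grid, make_layer):
        out = scale_lst(make_layer(small_grid, np.full((8, 8), 14825.0)))
        assert out.values[0, 0] == pytest.approx(23.35)

    def test_fill_value_becomes_nodata(self, small_grid, make_layer):
        dn = np.full((8, 8), 14825.0)
        dn[0, 0] = 0.0
        out = scale_lst(make_layer(small_grid, dn))
        assert out.nodata_mask[0, 0] and not out.nodata_mask[1, 1]

    def test_negative_dn_rejected(self, small_grid, make_layer):
        with pytest.raises(ValueError):
            scale_lst(make_layer(small_grid, np.full((8, 8), -1.0)))


class TestFilterDistribution:
    def test_constant_field_unchanged(self, small_grid, make_layer):
        layer = make_layer(small_grid, np.full((8, 8), 10.0))
        out = filter_distribution(layer, k_mad=5.0)
        assert not out.nodata_mask.any()

    def test_single_gross_outlier_removed(self, make_layer):
        grid = GridSpec("EPSG:32632", 0.0, 10_000.0, 1000.0, 10, 10)
        vals = np.full((10, 10), 10.0) + np.random.default_rng(0).normal(0, 0.1, (10, 10))
        vals[5, 5] = 80.0
        out = filter_distribution(make_layer(grid, vals), k_mad=5.0)
        assert out.nodata_mask[5, 5]
        assert int(out.nodata_mask.sum()) == 1

    def test_gaussian_rejection_rate_tiny(self, make_layer):
        grid = GridSpec("EPSG:32632", 0.0, 100_000.0, 1000.0, 100, 100)
        vals = np.random.default_rng(42).normal(15.0, 2.0, (100, 100))
        out = filter_distribution(make_layer(grid, vals), k_mad=5.0)
        # 5 MAD ~ 3.37 sigma: expected rejection well below 0.1%
        assert out.nodata_mask.mean() < 0.001

    def test_too_few_pixels_returns_unchanged(self, small_grid, make_layer):
        mask = np.ones((8, 8), dtype=bool)
        mask[0, :4] = False
        layer = make_layer(small_grid, np.full((8, 8), 9.0), mask)
        out = filter_distribution(layer, k_mad=5.0)
        np.testing.assert_array_equal(out.nodata_mask, mask)


class TestLapseModel:
    def test_exact_fit_on_noiseless_field(self, dem, linear_scene):
        model = fit_lapse_model(linear_scene, dem)
        assert model.slope == pytest.approx(-0.0065, abs=1e-12)
        assert model.intercept == pytest.approx(30.0, abs=1e-9)
        assert model.residual_sd == pytest.approx(0.0, abs=1e-9)

    def test_noisy_fit_within_sampling_error(self):
        grid = GridSpec("EPSG:32632", 0.0, 20_000.0, 200.0, 100, 100)
        rng = np.random.default_rng(12)
        elev = rng.uniform(0.0, 2500.0, grid.shape)
        lst = 30.0 - 0.0065 * elev + rng.normal(0.0, 1.0, grid.shape)
        dem = RasterLayer(grid=grid, values=elev, nodata_mask=np.zeros(grid.shape, bool))
        layer = RasterLayer(grid=grid, values=lst, nodata_mask=np.zeros(grid.shape, bool))
        model = fit_lapse_model(layer, dem)
        assert model.slope == pytest.approx(-0.0065, abs=5e-4)
        assert model.n_fit == 10_000

    def test_flat_dem_is_degenerate(self, small_grid, make_layer):
        dem = make_layer(small_grid, np.full((8, 8), 500.0))
        layer = make_layer(small_grid, np.random.default_rng(1).normal(size=(8, 8)))
        with pytest.raises(ValueError, match="degenerate"):
            fit_lapse_model(layer, dem)


class TestFilterLapseOutliers:
    def test_noiseless_field_untouched(self, dem, linear_scene):
        model = fit_lapse_model(linear_scene, dem)
        out = filter_lapse_outliers(linear_scene, dem, model, k_sigma=3.0)
        assert not out.nodata_mask.any()

    def test_implanted_anomalies_removed_exactly(self, dem):
        rng = np.random.default_rng(3)
        vals = 30.0 - 0.0065 * dem.values + rng.normal(0.0, 0.5, dem.grid.shape)
        layer = RasterLayer(grid=dem.grid, values=vals.copy(),
                            nodata_mask=np.zeros(dem.grid.shape, bool))
        model = fit_lapse_model(layer, dem)
        flat = rng.choice(vals.size, size=5, replace=False)
        anomalous = np.unravel_index(flat, vals.shape)
        vals[anomalous] += 20.0
        spiked = layer.replace(values=vals)
        out = filter_lapse_outliers(spiked, dem, model, k_sigma=3.0)
        removed = set(zip(*np.nonzero(out.nodata_mask)))
        expected = set(zip(*(idx.tolist() for idx in anomalous)))
        assert expected <= removed
        # A 3-sigma rule also clips ~0.3% of honest pixels; nothing more.
        assert len(removed) - len(expected) < 0.01 * vals.size

    def test_vacuous_threshold_removes_nothing(self, dem, linear_scene):
        rng = np.random.default_rng(9)
        noisy = linear_scene.replace(
            values=linear_scene.values + rng.normal(0, 1, dem.grid.shape)
        )
        model = fit_lapse_model(noisy, dem)
        out = filter_lapse_outliers(noisy, dem, model, k_sigma=1e9)
        assert not out.nodata_mask.any()

    def test_filtering_is_idempotent(self, dem):
        rng = np.random.default_rng(6)
        vals = 25.0 - 0.0065 * dem.values + rng.normal(0, 1.0, dem.grid.shape)
        layer = RasterLayer(grid=dem.grid, values=vals,
                            nodata_mask=np.zeros(dem.grid.shape, bool))
        model = fit_lapse_model(layer, dem)
        once = filter_lapse_outliers(layer, dem, model, k_sigma=3.0)
        twice = filter_lapse_outliers(once, dem, model, k_sigma=3.0)
        np.testing.assert_array_equal(once.nodata_mask, twice.nodata_mask)


class TestReconstructGaps:
    def test_exact_recovery_of_masked_linear_field(self, dem, linear_scene):
        rng = np.random.default_rng(21)
        mask = rng.random(dem.grid.shape) < 0.3
        gappy = linear_scene.replace(nodata_mask=mask)
        out = reconstruct_gaps(gappy, dem)
        assert not out.nodata_mask.any()
        np.testing.assert_allclose(out.values, linear_scene.values, atol=1e-6)

    def test_smooth_residual_bump_recovered(self, dem):
        x, y = dem.grid.cell_centers()
        span = dem.grid.n_cols * dem.grid.cell_size
        bump = 2.0 * np.sin(2 * np.pi * (x - dem.grid.origin_x) / span)
        truth = 28.0 - 0.0065 * dem.values + bump
        rng = np.random.default_rng(8)
        mask = rng.random(dem.grid.shape) < 0.2
        layer = RasterLayer(grid=dem.grid, values=truth, nodata_mask=mask)
        out = reconstruct_gaps(layer, dem)
        err = out.values[mask] - truth[mask]
        assert np.sqrt((err**2).mean()) < 0.5

    def test_no_gaps_is_identity(self, dem, linear_scene):
        out = reconstruct_gaps(linear_scene, dem)
        np.testing.assert_array_equal(out.values, linear_scene.values)

    def test_all_nodata_scene_fails(self, dem, linear_scene):
        gone = linear_scene.replace(nodata_mask=np.ones(dem.grid.shape, bool))
        with pytest.raises(ValueError):
            reconstruct_gaps(gone, dem, fit_lapse_model(linear_scene, dem))


class TestComposite8Day:
    def _acq(self, layer, date, sat="TERRA", op="DAY"):
        return LstAcquisition(layer.replace(timestamp=date), sat, op, date)

    def test_single_acquisition_passthrough(self, small_grid, make_layer):
        layer = make_layer(small_grid, np.full((8, 8), 12.0))
        out = composite_8day([self._acq(layer, dt.date(2020, 1, 3))], 1)
        np.testing.assert_array_equal(out.values, layer.values)

    def test_two_layer_mean(self, small_grid, make_layer):
        a = self._acq(make_layer(small_grid, np.full((8, 8), 10.0)), dt.date(2020, 1, 2))
        b = self._acq(make_layer(small_grid, np.full((8, 8), 20.0)), dt.date(2020, 1, 5))
        out = composite_8day([a, b], 1)
        assert np.allclose(out.values, 15.0)

    def test_pixel_valid_on_one_day_keeps_that_value(self, small_grid, make_layer):
        m = np.zeros((8, 8), bool)
        m[0, 0] = True
        a = self._acq(make_layer(small_grid, np.full((8, 8), 10.0), m), dt.date(2020, 1, 1))
        b = self._acq(make_layer(small_grid, np.full((8, 8), 20.0)), dt.date(2020, 1, 8))
        out = composite_8day([a, b], 1)
        assert out.values[0, 0] == 20.0
        assert out.values[1, 1] == 15.0

    def test_permutation_invariance(self, small_grid, make_layer):
        rng = np.random.default_rng(14)
        acqs = [
            self._acq(make_layer(small_grid, rng.normal(size=(8, 8)),
                                 rng.random((8, 8)) < 0.3),
                      dt.date(2020, 1, 1 + i))
            for i in range(6)
        ]
        fwd = composite_8day(acqs, 1)
        rev = composite_8day(acqs[::-1], 1)
        np.testing.assert_allclose(fwd.filled(), rev.filled(), equal_nan=True)

    def test_out_of_window_acquisition_rejected(self, small_grid, make_layer):
        late = self._acq(make_layer(small_grid, np.ones((8, 8))), dt.date(2020, 1, 12))
        with pytest.raises(ValueError):
            composite_8day([late], 1)

    def test_empty_window_is_an_error(self):
        with pytest.raises(ValueError):
            composite_8day([], 1)

    def test_46_windows_in_a_nonleap_year(self):
        windows = eight_day_windows(2021)
        assert len(windows) == 46
        assert windows[0][0] == dt.date(2021, 1, 1)
        assert (windows[-1][1] - windows[-1][0]).days == 5


class TestLocalChain:
    def test_emits_four_gapfree_layers_per_day(self, config, dem, lst_scene):
        out = process_local_day(lst_scene.acquisitions, lst_scene.qc, dem)
        assert len(out) == 4
        assert {l.hour_tag for l in out} == {
            "TERRA-DAY", "TERRA-NIGHT", "AQUA-DAY", "AQUA-NIGHT"
        }
        for layer in out:
            assert not layer.nodata_mask.any()

    def test_reconstruction_tracks_truth(self, config, dem, lst_scene):
        out = process_local_day(lst_scene.acquisitions, lst_scene.qc, dem)
        for layer in out:
            truth = lst_scene.truth[layer.hour_tag].values
            rmse = np.sqrt(((layer.values - truth) ** 2).mean())
            assert rmse < 2.0 * config.noise_sd
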