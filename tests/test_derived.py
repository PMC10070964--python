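"""Derived covariates: GDD, aridity, rainy days, variability, bioclim, zonal cover."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
import shapely

from envgrid.derived import (
    BIOCLIM_NAMES,
    DailyClimateSeries,
    MonthlyClimate,
    bioclim,
    de_martonne,
    de_martonne_monthly,
    gdd,
    landcover_percent,
    monthly_climate_from_daily,
    rainy_days,
    windowed_variability,
)
from envgrid.grids import RasterLayer


def daily(tmin=None, tmax=None, prec=None, start=dt.date(2020, 1, 1)):
    n = max(len(v) for v in (tmin, tmax, prec) if v is not None)
    idx = pd.date_range(start, periods=n, freq="D")
    data = {}
    if tmin is not None:
        data["tmin"] = tmin
    if tmax is not None:
        data["tmax"] = tmax
    if prec is not None:
        data["prec"] = prec
    return DailyClimateSeries(pd.DataFrame(data, index=idx))


class TestGdd:
    def test_ten_constant_days(self):
        series = daily(tmin=[10.0] * 10, tmax=[20.0] * 10)
        out = gdd(series, 10.0, (dt.date(2020, 1, 1), dt.date(2020, 1, 10)))
        assert out.value == pytest.approx(50.0)
        assert out.n_days_missing == 0

    def test_all_days_below_base_accumulate_zero(self):
        series = daily(tmin=[-5.0] * 7, tmax=[3.0] * 7)
        out = gdd(series, 10.0, (dt.date(2020, 1, 1), dt.date(2020, 1, 7)))
        assert out.value == 0.0

    def test_very_low_base_reduces_to_mean_sum(self):
        rng = np.random.default_rng(0)
        tmin = rng.uniform(0, 10, 15)
        tmax = tmin + rng.uniform(2, 10, 15)
        series = daily(tmin=tmin, tmax=tmax)
        period = (dt.date(2020, 1, 1), dt.date(2020, 1, 15))
        out = gdd(series, -100.0, period)
        expected = ((tmin + tmax) / 2).sum() + 100.0 * 15
        assert out.value == pytest.approx(expected)

    def test_missing_days_skipped_and_reported(self):
        tmin = [10.0, np.nan, 10.0]
        tmax = [20.0, 20.0, 20.0]
        series = daily(tmin=tmin, tmax=tmax)
        out = gdd(series, 10.0, (dt.date(2020, 1, 1), dt.date(2020, 1, 3)))
        assert out.value == pytest.approx(10.0)
        assert out.n_days_missing == 1

    def test_additive_over_partitioned_ranges(self):
        rng = np.random.default_rng(5)
        tmin = rng.uniform(5, 15, 30)
        series = daily(tmin=tmin, tmax=tmin + 8)
        whole = gdd(series, 10.0, (dt.date(2020, 1, 1), dt.date(2020, 1, 30)))
        first = gdd(series, 10.0, (dt.date(2020, 1, 1), dt.date(2020, 1, 14)))
        second = gdd(series, 10.0, (dt.date(2020, 1, 15), dt.date(2020, 1, 30)))
        assert whole.value == pytest.approx(first.value + second.value)

    def test_empty_period_is_an_error(self):
        series = daily(tmin=[1.0], tmax=[2.0])
        with pytest.raises(ValueError):
            gdd(series, 10.0, (dt.date(2020, 2, 1), dt.date(2020, 1, 1)))


class TestDeMartonne:
    def test_worked_example(self):
        assert de_martonne(600.0, 20.0) == pytest.approx(20.0)

    def test_zero_precipitation(self):
        assert de_martonne(0.0, 5.0) == 0.0

    def test_pole_of_formula_is_nodata(self):
        assert np.isnan(de_martonne(100.0, -10.0))

    def test_monthly_variant(self):
        assert de_martonne_monthly(50.0, 20.0) == pytest.approx(20.0)


class TestRainyDays:
    def test_count_by_hand(self):
        series = daily(prec=[0.0, 0.1, 1.0, 5.0, 0.0])
        assert rainy_days(series, 1.0) == 2

    def test_zero_threshold_counts_every_day(self):
        series = daily(prec=[0.0, 0.5, 2.0])
        assert rainy_days(series, 0.0) == 3

    def test_dry_series(self):
        series = daily(prec=[0.0] * 10)
        assert rainy_days(series, 1.0) == 0

    def test_monotone_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(3)
        series = daily(prec=rng.exponential(2.0, 60))
        counts = [rainy_days(series, thr) for thr in (0.0, 0.5, 1.0, 2.0, 5.0, 10.0)]
        assert counts == sorted(counts, reverse=True)

    def test_strict_mode(self):
        series = daily(prec=[1.0, 1.0, 2.0])
        assert rainy_days(series, 1.0, strict=True) == 1


class TestWindowedVariability:
    def _layers(self, series, grid):
        return [
            RasterLayer(grid=grid, values=np.full(grid.shape, v),
                        nodata_mask=np.zeros(grid.shape, bool), variable="NDVI")
            for v in series
        ]

    def test_constant_series(self, small_grid):
        sd, kurt = windowed_variability(self._layers([5.0] * 6, small_grid))
        assert np.allclose(sd.values, 0.0)
        assert kurt.nodata_mask.all()  # zero variance

    def test_two_point_distribution_closed_form(self, small_grid):
        sd, kurt = windowed_variability(self._layers([1.0, 1.0, -1.0, -1.0], small_grid))
        assert np.allclose(sd.values, np.sqrt(4.0 / 3.0))
        assert np.allclose(kurt.values, -2.0)

    def test_gaussian_excess_kurtosis_near_zero(self, small_grid):
        rng = np.random.default_rng(8)
        layers = [
            RasterLayer(grid=small_grid, values=rng.normal(0, 1, small_grid.shape),
                        nodata_mask=np.zeros(small_grid.shape, bool))
            for _ in range(4000)
        ]
        _, kurt = windowed_variability(layers)
        assert np.abs(kurt.values.mean()) < 0.1

    def test_minimum_observation_requirements(self, small_grid):
        layers = self._layers([1.0, 2.0, 3.0], small_grid)
        mask = np.zeros(small_grid.shape, bool)
        mask[0, 0] = True
        layers[0] = layers[0].replace(nodata_mask=mask)
        layers[1] = layers[1].replace(nodata_mask=mask)
        sd, kurt = windowed_variability(layers)
        assert sd.nodata_mask[0, 0]  # only one valid observation there
        assert kurt.nodata_mask.all()  # nowhere reaches 4 observations

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            windowed_variability([])


def brute_force_bioclim(tmin, tmax, prec):
    """Independent oracle: explicit loops over all 12 wrap-around quarters."""
    tmean = (np.asarray(tmin) + np.asarray(tmax)) / 2.0
    tmin, tmax, prec = (np.asarray(a, float) for a in (tmin, tmax, prec))
    quarters = [[(m + j) % 12 for j in range(3)] for m in range(12)]
    qp = [sum(prec[i] for i in q) for q in quarters]
    qt = [sum(tmean[i] for i in q) / 3.0 for q in quarters]

    def argbest(vals, best):
        target = best(vals)
        return min(i for i, v in enumerate(vals) if v == target)

    wet, dry = argbest(qp, max), argbest(qp, min)
    warm, cold = argbest(qt, max), argbest(qt, min)
    out = {
        "BIO1": tmean.mean(),
        "BIO2": float(np.mean(tmax - tmin)),
        "BIO4": 100.0 * float(np.std(tmean, ddof=1)),
        "BIO5": tmax.max(),
        "BIO6": tmin.min(),
        "BIO12": prec.sum(),
        "BIO13": prec.max(),
        "BIO14": prec.min(),
        "BIO15": 100.0 * float(np.std(prec, ddof=1)) / (prec.mean() + 1.0),
        "BIO8": qt[wet], "BIO9": qt[dry], "BIO10": qt[warm], "BIO11": qt[cold],
        "BIO16": qp[wet], "BIO17": qp[dry], "BIO18": qp[warm], "BIO19": qp[cold],
    }
    out["BIO7"] = out["BIO5"] - out["BIO6"]
    out["BIO3"] = 100.0 * out["BIO2"] / out["BIO7"] if out["BIO7"] != 0 else np.nan
    return out


class TestBioclim:
    def test_constant_climate(self):
        monthly = MonthlyClimate(np.full(12, 10.0), np.full(12, 10.0), np.full(12, 50.0))
        out = bioclim(monthly)
        assert out["BIO1"] == 10.0
        assert out["BIO2"] == 0.0
        assert out["BIO4"] == 0.0
        assert out["BIO5"] == 10.0 and out["BIO6"] == 10.0 and out["BIO7"] == 0.0
        assert np.isnan(out["BIO3"])
        assert out["BIO12"] == 600.0
        assert out["BIO13"] == 50.0 and out["BIO14"] == 50.0
        assert out["BIO15"] == 0.0

    def test_emits_exactly_19_variables(self):
        rng = np.random.default_rng(0)
        monthly = MonthlyClimate(rng.uniform(-5, 10, 12), rng.uniform(10, 25, 12),
                                 rng.uniform(0, 120, 12))
        out = bioclim(monthly)
        assert tuple(out.keys()) == BIOCLIM_NAMES
        assert len(out) == 19

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            tmin = rng.uniform(-10, 10, 12)
            tmax = tmin + rng.uniform(0.5, 15, 12)
            prec = rng.uniform(0, 200, 12)
            got = bioclim(MonthlyClimate(tmin, tmax, prec))
            want = brute_force_bioclim(tmin, tmax, prec)
            for name in BIOCLIM_NAMES:
                np.testing.assert_allclose(got[name], want[name], rtol=1e-10,
                                           err_msg=name)

    def test_internal_identities_on_random_inputs(self):
        rng = np.random.default_rng(23)
        tmin = rng.uniform(-10, 5, (12, 6, 6))
        tmax = tmin + rng.uniform(1, 12, (12, 6, 6))
        prec = rng.uniform(0, 150, (12, 6, 6))
        out = bioclim(MonthlyClimate(tmin, tmax, prec))
        np.testing.assert_allclose(out["BIO7"], out["BIO5"] - out["BIO6"])
        np.testing.assert_allclose(out["BIO13"], prec.max(axis=0))
        assert np.all(out["BIO16"] >= 3.0 * out["BIO14"] - 1e-9)
        assert np.all(out["BIO13"] >= out["BIO14"])
        assert np.all(out["BIO16"] >= out["BIO17"])

    def test_commutes_with_spatial_cropping(self):
        rng = np.random.default_rng(29)
        tmin = rng.uniform(-5, 5, (12, 8, 8))
        tmax = tmin + rng.uniform(1, 10, (12, 8, 8))
        prec = rng.uniform(0, 100, (12, 8, 8))
        full = bioclim(MonthlyClimate(tmin, tmax, prec))
        crop = bioclim(MonthlyClimate(tmin[:, :4, :4], tmax[:, :4, :4], prec[:, :4, :4]))
        for name in BIOCLIM_NAMES:
            np.testing.assert_allclose(full[name][:4, :4], crop[name], equal_nan=True)

    def test_incomplete_months_rejected_with_listing(self):
        tmin = np.full(12, 5.0)
        tmin[[2, 7]] = np.nan
        with pytest.raises(ValueError, match=r"\[3, 8\]"):
            bioclim(MonthlyClimate(tmin, np.full(12, 15.0), np.full(12, 30.0)))


class TestMonthlyFromDaily:
    def test_complete_year(self):
        idx = pd.date_range("2021-01-01", "2021-12-31", freq="D")
        df = pd.DataFrame(
            {"tmin": 5.0, "tmax": 15.0, "prec": 2.0}, index=idx
        )
        monthly = monthly_climate_from_daily(DailyClimateSeries(df), 2021)
        assert np.allclose(monthly.tmin, 5.0)
        assert monthly.prec[0] == pytest.approx(62.0)  # 31 days x 2 mm
        assert monthly.missing_months() == []

    def test_sparse_month_marked_missing(self):
        idx = pd.date_range("2021-01-01", "2021-12-31", freq="D")
        df = pd.DataFrame({"tmin": 5.0, "tmax": 15.0, "prec": 1.0}, index=idx)
        df.loc["2021-06-01":"2021-06-20", "tmax"] = np.nan  # > 20% of June gone
        monthly = monthly_climate_from_daily(DailyClimateSeries(df), 2021)
        assert 6 in monthly.missing_months()


class TestLandcoverPercent:
    def _classes(self, small_grid, values):
        return RasterLayer(grid=small_grid, values=np.asarray(values, float),
                           nodata_mask=np.zeros(small_grid.shape, bool),
                           variable="LANDCOVER")

    def test_single_class_single_zone(self, small_grid):
        classes = self._classes(small_grid, np.full((8, 8), 3.0))
        zones = RasterLayer(grid=small_grid, values=np.ones((8, 8)),
                            nodata_mask=np.zeros((8, 8), bool))
        table = landcover_percent(classes, zones)
        assert len(table) == 1
        assert table.iloc[0]["percent"] == 100.0

    def test_checkerboard_splits_fifty_fifty(self, small_grid):
        rows, cols = np.indices((8, 8))
        classes = self._classes(small_grid, np.where((rows + cols) % 2 == 0, 1, 2))
        zones = RasterLayer(grid=small_grid, values=np.ones((8, 8)),
                            nodata_mask=np.zeros((8, 8), bool))
        table = landcover_percent(classes, zones)
        assert sorted(table["percent"]) == [50.0, 50.0]

    def test_percentages_sum_to_100_per_zone(self, small_grid):
        rng = np.random.default_rng(2)
        classes = self._classes(small_grid, rng.integers(1, 5, (8, 8)))
        zones = RasterLayer(grid=small_grid, values=rng.integers(1, 4, (8, 8)).astype(float),
                            nodata_mask=np.zeros((8, 8), bool))
        table = landcover_percent(classes, zones)
        sums = table.groupby("zone")["percent"].sum()
        assert np.allclose(sums, 100.0, atol=1e-9)

    def test_polygon_zone_outside_raster_is_empty(self, small_grid):
        classes = self._classes(small_grid, np.ones((8, 8)))
        far = shapely.box(0.0, 0.0, 100.0, 100.0)
        table = landcover_percent(classes, {"nowhere": far})
        assert table.empty

    def test_polygon_half_cover(self, small_grid):
        classes = self._classes(small_grid, np.ones((8, 8)))
        xmin, ymin, xmax, ymax = small_grid.bounds
        west = shapely.box(xmin, ymin, (xmin + xmax) / 2, ymax)
        table = landcover_percent(classes, {"west": west})
        assert table.iloc[0]["percent"] == 100.0  # single class, half the cells
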