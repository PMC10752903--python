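"""JJA means, NIRv, regional averaging, anomalies, normalization, regridding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gppshift import (RegionalSeries, RegionBox, anomalize, cell_areas,
                      compute_nirv, jja_mean, normalize, regional_average, regrid)
from gppshift.errors import (DegenerateSeriesError, DimensionError,
                             ExtrapolationError, PeriodError, RegionError)


def monthly_time(start_year, n_years):
    return pd.date_range(f"{start_year}-01-01", periods=12 * n_years, freq="MS")


class TestJJAMean:
    def test_constant_field(self, field_factory):
        time = monthly_time(2000, 3)
        field = field_factory(np.full((36, 2, 2), 4.5), time=time)
        out = jja_mean(field)
        assert list(out["year"].values) == [2000, 2001, 2002]
        assert np.allclose(out.values, 4.5)

    def test_simple_arithmetic(self, field_factory):
        time = monthly_time(2000, 1)
        vals = np.zeros((12, 1, 1))
        vals[5], vals[6], vals[7] = 1.0, 2.0, 3.0  # Jun, Jul, Aug
        out = jja_mean(field_factory(vals, time=time))
        assert out.values.squeeze() == pytest.approx(2.0)

    def test_matches_three_month_oracle(self, field_factory, rng):
        time = monthly_time(1990, 4)
        vals = rng.standard_normal((48, 3, 2))
        out = jja_mean(field_factory(vals, time=time))
        for k, year in enumerate(range(1990, 1994)):
            expected = vals[12 * k + 5: 12 * k + 8].mean(axis=0)
            assert np.allclose(out.sel(year=year).values, expected)

    def test_incomplete_year_dropped(self, field_factory):
        time = monthly_time(2000, 2)[:19]  # 2001 ends in July: no August
        vals = np.ones((19, 1, 1))
        out = jja_mean(field_factory(vals, time=time))
        assert list(out["year"].values) == [2000]


class TestNIRv:
    def test_soil_offset_cancels(self, field_factory):
        time = monthly_time(2000, 1)
        ndvi = field_factory(np.full((12, 2, 2), 0.08), time=time, units="1")
        nirt = field_factory(np.random.default_rng(0).random((12, 2, 2)),
                             time=time, units="1")
        assert np.allclose(compute_nirv(ndvi, nirt).values, 0.0)

    def test_arithmetic(self, field_factory):
        time = monthly_time(2000, 1)
        ndvi = field_factory(np.full((12, 1, 1), 0.58), time=time, units="1")
        nirt = field_factory(np.full((12, 1, 1), 0.30), time=time, units="1")
        assert compute_nirv(ndvi, nirt).values.flat[0] == pytest.approx(0.15)

    def test_zero_nirt(self, field_factory):
        time = monthly_time(2000, 1)
        ndvi = field_factory(np.random.default_rng(1).random((12, 1, 1)),
                             time=time, units="1")
        nirt = field_factory(np.zeros((12, 1, 1)), time=time, units="1")
        assert np.allclose(compute_nirv(ndvi, nirt).values, 0.0)

    def test_grid_mismatch(self, field_factory):
        time = monthly_time(2000, 1)
        ndvi = field_factory(np.ones((12, 2, 2)), time=time, units="1")
        nirt = field_factory(np.ones((12, 2, 2)), time=time, units="1",
                             lat=np.array([50.0, 51.0]))
        with pytest.raises(DimensionError):
            compute_nirv(ndvi, nirt)


class TestRegionalAverage:
    def test_constant_field_mean(self, field_factory):
        field = field_factory(np.full((5, 4, 4), 7.25))
        box = RegionBox(29.5, 33.5, 99.5, 103.5)
        series = regional_average(field, box)
        assert np.allclose(series.values, 7.25)
        assert series.variant == "raw"

    def test_cosine_weighting_forced(self, field_factory):
        """Cells at 0 and 60 degrees N with values 0 and 1: the weighted
        mean is cos(60)/(cos(0)+cos(60)) = 1/3."""
        field = field_factory(np.array([[[0.0], [1.0]]]),
                              lat=np.array([0.0, 60.0]), lon=np.array([100.0]),
                              years=np.array([2000]))
        series = regional_average(field, RegionBox(-1, 61, 99, 101))
        assert series.values[0] == pytest.approx(1 / 3, abs=1e-12)

    def test_single_cell_total_matches_spherical_area(self, field_factory):
        from oracles import spherical_cell_area

        field = field_factory(np.full((2, 3, 3), 2.0),
                              lat=np.array([40.0, 41.0, 42.0]),
                              lon=np.array([110.0, 111.0, 112.0]))
        series = regional_average(field, RegionBox(40.5, 41.5, 110.5, 111.5),
                                  mode="total")
        expected = 2.0 * spherical_cell_area(41.0, 1.0, 1.0) * 1e-12
        assert series.values[0] == pytest.approx(expected, rel=1e-12)
        assert series.units == "TgC month-1"

    def test_missing_cells_excluded_from_weights(self, field_factory):
        vals = np.full((1, 2, 2), 3.0)
        vals[0, 0, 0] = np.nan
        field = field_factory(vals, years=np.array([2000]))
        series = regional_average(field, RegionBox(29, 32, 99, 102))
        assert series.values[0] == pytest.approx(3.0)

    def test_empty_box(self, field_factory):
        field = field_factory(np.ones((1, 2, 2)))
        with pytest.raises(RegionError):
            regional_average(field, RegionBox(80, 85, 0, 5))

    def test_commutes_with_jja_mean(self, field_factory, rng):
        """Regional mean of the JJA field equals the JJA mean of the
        monthly regional series (same weights both ways)."""
        time = monthly_time(2000, 3)
        field = field_factory(rng.standard_normal((36, 4, 3)), time=time)
        box = RegionBox(29.5, 33.5, 99.5, 102.5)
        a = regional_average(jja_mean(field), box)
        monthly = regional_average(field, box)  # pandas Series
        jja = monthly[monthly.index.month.isin([6, 7, 8])]
        b = jja.groupby(jja.index.year).mean()
        assert np.allclose(a.values, b.values, atol=1e-10)

    def test_cell_areas_sum_over_globe(self):
        lat = np.arange(-89.5, 90, 1.0)
        lon = np.arange(0.5, 360, 1.0)
        total = float(cell_areas(lat, lon).sum())
        assert total == pytest.approx(4 * np.pi * 6.371e6 ** 2, rel=1e-6)


class TestAnomalize:
    def test_constant_series_zeroed(self):
        s = RegionalSeries(np.arange(2000, 2005), np.full(5, 2.5))
        assert np.allclose(anomalize(s).values, 0.0)

    def test_simple_example(self):
        s = RegionalSeries(np.arange(2000, 2003), [1.0, 2.0, 3.0])
        assert np.allclose(anomalize(s).values, [-1, 0, 1])

    def test_baseline_mean_is_zero(self, rng):
        s = RegionalSeries(np.arange(1990, 2010), rng.standard_normal(20))
        out = anomalize(s, baseline=range(1995, 2000))
        mask = np.isin(out.years, range(1995, 2000))
        assert abs(out.values[mask].mean()) < 1e-12
        assert out.variant == "anomaly"

    def test_empty_baseline(self):
        s = RegionalSeries(np.arange(2000, 2005), np.arange(5.0))
        with pytest.raises(PeriodError):
            anomalize(s, baseline=range(1980, 1990))


class TestNormalize:
    def test_two_point_example(self):
        s = RegionalSeries(np.array([2000, 2001]), [0.0, 2.0])
        out = normalize(s)
        assert np.allclose(out.values, [-np.sqrt(0.5), np.sqrt(0.5)], atol=1e-4)
        assert out.variant == "normalized"

    @given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=30))
    def test_mean_sd_and_idempotence(self, values):
        values = np.asarray(values)
        if np.std(values, ddof=1) < 1e-6:
            return
        s = RegionalSeries(np.arange(2000, 2000 + len(values)), values)
        z = normalize(s)
        assert abs(z.values.mean()) < 1e-10
        assert abs(np.std(z.values, ddof=1) - 1) < 1e-10
        z2 = normalize(z.copy_with(variant="raw"))
        assert np.allclose(z2.values, z.values, atol=1e-12)

    def test_affine_invariance(self, rng):
        values = rng.standard_normal(15)
        s1 = RegionalSeries(np.arange(15) + 2000, values)
        s2 = RegionalSeries(np.arange(15) + 2000, 3.7 * values - 11.0)
        assert np.allclose(normalize(s1).values, normalize(s2).values, atol=1e-12)

    def test_zero_variance(self):
        s = RegionalSeries(np.arange(2000, 2004), np.full(4, 1.0))
        with pytest.raises(DegenerateSeriesError):
            normalize(s)


class TestRegrid:
    def test_identity_when_on_target_grid(self, field_factory):
        lat = np.arange(30.5, 34, 1.0)
        lon = np.arange(100.5, 104, 1.0)
        field = field_factory(np.random.default_rng(2).random((2, 4, 4)),
                              lat=lat, lon=lon)
        assert regrid(field, 1.0) is field

    def test_constant_preserved(self, field_factory):
        lat = np.arange(30.25, 34, 0.5)
        lon = np.arange(100.25, 104, 0.5)
        field = field_factory(np.full((2, len(lat), len(lon)), 5.0), lat=lat, lon=lon)
        out = regrid(field, 1.0)
        assert np.allclose(out.values, 5.0)

    def test_bilinear_exact_on_planar_field(self, field_factory):
        lat = np.arange(30.25, 36, 0.5)
        lon = np.arange(100.25, 108, 0.5)
        plane = 2.0 * lat[:, None] + 0.5 * lon[None, :]
        field = field_factory(np.broadcast_to(plane, (3,) + plane.shape).copy(),
                              lat=lat, lon=lon)
        out = regrid(field, 1.0)
        expected = (2.0 * out["lat"].values[:, None]
                    + 0.5 * out["lon"].values[None, :])
        assert np.allclose(out.values, expected, atol=1e-10)

    def test_extrapolation_error(self, field_factory):
        lat = np.arange(30.25, 32, 0.5)
        lon = np.arange(100.25, 102, 0.5)
        field = field_factory(np.ones((1, len(lat), len(lon))), lat=lat, lon=lon)
        with pytest.raises(ExtrapolationError):
            regrid(field, 1.0, lat=np.array([29.0, 31.0]), lon=np.array([101.0]))
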