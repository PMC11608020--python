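import datetime
import logging
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import oracle_net_radiation
from etcalib import meteorology as met
from etcalib.meteorology import DailyWeatherRecord, StationMeta, VapourPressures


class TestSaturationVapourPressure:
    def test_at_zero(self):
        assert met.saturation_vapour_pressure(0.0) == pytest.approx(0.6108)

    def test_at_20(self):
        # frozen from the direct arithmetic oracle 0.6108*exp(17.27*20/257.3)
        assert met.saturation_vapour_pressure(20.0) == pytest.approx(
            2.338281270927446, abs=1e-9)

    def test_at_30(self):
        assert met.saturation_vapour_pressure(30.0) == pytest.approx(
            4.243065058759013, abs=1e-9)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            met.saturation_vapour_pressure(float("nan"))

    def test_rejects_below_pole(self):
        with pytest.raises(ValueError):
            met.saturation_vapour_pressure(-240.0)

    @given(st.floats(-20, 50), st.floats(1e-6, 5.0))
    @settings(max_examples=100, deadline=None)
    def test_strictly_increasing(self, t, dt):
        assert (met.saturation_vapour_pressure(t + dt)
                > met.saturation_vapour_pressure(t))

    def test_vectorised(self):
        out = met.saturation_vapour_pressure(np.array([0.0, 20.0]))
        assert out.shape == (2,)
        assert out[0] == pytest.approx(0.6108)


class TestMeanSaturationVapourPressure:
    @given(st.floats(-20, 50))
    @settings(max_examples=50, deadline=None)
    def test_collapses_to_single_temperature(self, t):
        assert met.mean_saturation_vapour_pressure(t, t) == pytest.approx(
            met.saturation_vapour_pressure(t))

    def test_mixed(self):
        assert met.mean_saturation_vapour_pressure(30.0, 20.0) == pytest.approx(
            3.2906731648432297, abs=1e-9)

    def test_both_zero(self):
        assert met.mean_saturation_vapour_pressure(0.0, 0.0) == pytest.approx(0.6108)

    def test_rejects_inverted(self):
        with pytest.raises(ValueError):
            met.mean_saturation_vapour_pressure(10.0, 20.0)


class TestActualVapourPressure:
    def test_saturation_limit(self):
        ea = met.actual_vapour_pressure(30.0, 20.0, 100.0, 100.0)
        assert ea == pytest.approx(
            met.mean_saturation_vapour_pressure(30.0, 20.0))

    def test_dry_limit(self):
        assert met.actual_vapour_pressure(30.0, 20.0, 0.0, 0.0) == 0.0

    def test_derived_example(self):
        # (es(20)*0.8 + es(30)*0.4)/2, frozen from the arithmetic oracle
        assert met.actual_vapour_pressure(30.0, 20.0, 80.0, 40.0) == pytest.approx(
            1.7839255201227813, abs=1e-9)

    def test_rejects_out_of_range_humidity(self):
        with pytest.raises(ValueError):
            met.actual_vapour_pressure(30.0, 20.0, 120.0, 40.0)


class TestVapourPressureDeficit:
    def test_zero(self):
        assert met.vapour_pressure_deficit(2.0, 2.0) == 0.0

    def test_derived(self):
        assert met.vapour_pressure_deficit(
            3.2906731648432297, 1.7839255201227813
        ) == pytest.approx(1.5067476447204484, abs=1e-9)

    def test_negative_propagated_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING, logger="etcalib.meteorology"):
            out = met.vapour_pressure_deficit(1.0, 1.2)
        assert out == pytest.approx(-0.2)
        assert any("negative" in r.message for r in caplog.records)

    def test_rejects_negative_pressure(self):
        with pytest.raises(ValueError):
            met.vapour_pressure_deficit(-1.0, 0.5)

    def test_ea_bounded_by_es_on_physical_records(self, season_records):
        for rec in season_records:
            vp = VapourPressures.from_record(rec)
            assert vp.ea <= vp.es + 1e-12


class TestSlopeSaturationCurve:
    def test_at_study_temperature(self):
        assert met.slope_saturation_curve(21.5) == pytest.approx(
            0.15690345906391898, abs=1e-9)

    def test_at_zero(self):
        assert met.slope_saturation_curve(0.0) == pytest.approx(
            0.04445038286283265, abs=1e-9)

    def test_monotone(self):
        assert met.slope_saturation_curve(25.0) > met.slope_saturation_curve(15.0)


class TestPsychrometricConstant:
    def test_sea_level(self):
        assert met.atmospheric_pressure(0.0) == pytest.approx(101.3)
        assert met.psychrometric_constant(0.0) == pytest.approx(0.0673645,
                                                                abs=1e-9)

    def test_station_elevation(self):
        assert met.psychrometric_constant(1669.0) == pytest.approx(
            0.05523885137103971, abs=1e-9)

    def test_decreases_with_elevation(self):
        assert met.psychrometric_constant(2000.0) < met.psychrometric_constant(0.0)


class TestNetRadiation:
    def test_shortwave_vanishes_at_zero_rs(self, station):
        rn = met.net_radiation(0.0, 30.0, 15.0, 1.5, station, 196)
        # pure (negative of) longwave loss: must be <= 0 with ratio floor
        rnl = 4.903e-9 * ((303.16 ** 4 + 288.16 ** 4) / 2) \
            * (0.34 - 0.14 * math.sqrt(1.5)) * (1.35 * 0.0 - 0.35)
        assert rn == pytest.approx(-rnl, abs=1e-12)

    def test_staged_oracle_example(self, station):
        rn = met.net_radiation(24.0, 30.0, 15.0, 1.5, station, 196)
        assert rn == pytest.approx(14.275915059785321, abs=1e-9)

    def test_matches_oracle_on_random_inputs(self, station):
        rng = np.random.default_rng(42)
        for _ in range(100):
            doy = int(rng.integers(91, 305))
            tmin = float(rng.uniform(-5, 20))
            tmax = tmin + float(rng.uniform(0.5, 18))
            ea = float(rng.uniform(0.1, 3.0))
            rs = float(rng.uniform(0.0, 32.0))
            got = met.net_radiation(rs, tmax, tmin, ea, station, doy)
            want = oracle_net_radiation(rs, tmax, tmin, ea, station.latitude,
                                        station.elevation, doy)
            assert got == pytest.approx(want, abs=1e-9)

    def test_increasing_in_rs(self, station):
        vals = [met.net_radiation(rs, 30.0, 15.0, 1.5, station, 196)
                for rs in (5.0, 15.0, 25.0)]
        assert vals[0] < vals[1] < vals[2]

    def test_polar_night_with_radiation_rejected(self):
        polar = StationMeta(latitude=80.0, elevation=0.0)
        with pytest.raises(ValueError):
            met.net_radiation(5.0, 0.0, -10.0, 0.3, polar, 355)

    def test_doy_bounds(self, station):
        with pytest.raises(ValueError):
            met.extraterrestrial_radiation(station.latitude, 0)
        with pytest.raises(ValueError):
            met.extraterrestrial_radiation(station.latitude, 367)


class TestConversions:
    def test_kpa_to_hpa(self):
        assert met.convert_pressure(1.0, "hPa") == pytest.approx(10.0)

    def test_kpa_to_mmhg(self):
        assert met.convert_pressure(1.0, "mmHg") == pytest.approx(
            7.500616827041697, abs=1e-12)

    def test_zero(self):
        assert met.convert_pressure(0.0, "hPa") == 0.0
        assert met.convert_pressure(0.0, "mmHg") == 0.0
        assert met.convert_wind_to_miles_per_day(0.0) == 0.0

    def test_unknown_unit(self):
        with pytest.raises(ValueError):
            met.convert_pressure(1.0, "psi")

    def test_wind_unit(self):
        assert met.convert_wind_to_miles_per_day(1.0) == pytest.approx(
            53.686471009305656, abs=1e-9)
        assert met.convert_wind_to_miles_per_day(2.65) == pytest.approx(
            142.26914817466, abs=1e-9)

    def test_negative_wind_rejected(self):
        with pytest.raises(ValueError):
            met.convert_wind_to_miles_per_day(-0.1)

    @given(st.floats(-50, 50), st.floats(-50, 50))
    @settings(max_examples=50, deadline=None)
    def test_pressure_conversion_linear(self, a, b):
        for unit in ("hPa", "mmHg"):
            assert met.convert_pressure(a + b, unit) == pytest.approx(
                met.convert_pressure(a, unit) + met.convert_pressure(b, unit),
                abs=1e-9)

    @given(st.floats(0, 50), st.floats(0, 50))
    @settings(max_examples=50, deadline=None)
    def test_wind_conversion_linear(self, a, b):
        assert met.convert_wind_to_miles_per_day(a + b) == pytest.approx(
            met.convert_wind_to_miles_per_day(a)
            + met.convert_wind_to_miles_per_day(b), abs=1e-9)


class TestWindProfile:
    def test_passthrough_at_2m(self):
        assert met.wind_at_2m(3.1, 2.0) == 3.1

    def test_10m_correction(self):
        expected = 3.0 * 4.87 / math.log(67.8 * 10.0 - 5.42)
        assert met.wind_at_2m(3.0, 10.0) == pytest.approx(expected)

    def test_bad_height(self):
        with pytest.raises(ValueError):
            met.wind_at_2m(3.0, 0.0)


class TestSampleSkewness:
    def test_symmetric(self):
        assert met.sample_skewness([1.0, 2.0, 3.0]) == pytest.approx(0.0, abs=1e-12)

    def test_brute_force_example(self):
        # frozen from an independent spreadsheet-formula computation
        assert met.sample_skewness([1, 2, 3, 4, 10]) == pytest.approx(
            1.697056274847714, abs=1e-12)

    @given(st.lists(st.floats(-100, 100), min_size=4, max_size=30),
           st.floats(0.1, 10), st.floats(-5, 5))
    @settings(max_examples=50, deadline=None)
    def test_affine_invariance(self, xs, c, d):
        x = np.asarray(xs)
        if x.std(ddof=1) < 1e-6:
            return
        assert met.sample_skewness(c * x + d) == pytest.approx(
            met.sample_skewness(x), rel=1e-6, abs=1e-9)

    def test_too_short(self):
        with pytest.raises(ValueError):
            met.sample_skewness([1.0, 2.0])

    def test_zero_variance(self):
        with pytest.raises(ValueError):
            met.sample_skewness([2.0, 2.0, 2.0])


class TestDomainTypes:
    def test_record_temperature_ordering(self):
        with pytest.raises(ValueError):
            DailyWeatherRecord(date=datetime.date(2020, 6, 1), tmax=10.0,
                               tmin=15.0, tmean=12.0, rhmax=80.0, rhmin=30.0,
                               rhmean=50.0, rs=20.0, u2=2.0)

    def test_record_humidity_bounds(self):
        with pytest.raises(ValueError):
            DailyWeatherRecord(date=datetime.date(2020, 6, 1), tmax=25.0,
                               tmin=10.0, tmean=18.0, rhmax=120.0, rhmin=30.0,
                               rhmean=50.0, rs=20.0, u2=2.0)

    def test_station_bounds(self):
        with pytest.raises(ValueError):
            StationMeta(latitude=95.0, elevation=100.0)
        with pytest.raises(ValueError):
            StationMeta(latitude=38.0, elevation=-500.0)
        with pytest.raises(ValueError):
            StationMeta(latitude=38.0, elevation=100.0, anemometer_height=0.0)

    def test_vapour_pressures_from_record(self, toy_records):
        vp = VapourPressures.from_record(toy_records[0])
        assert vp.es == pytest.approx((vp.es_max + vp.es_min) / 2)
        assert vp.vpd == pytest.approx(vp.es - vp.ea)
        assert vp.es_min <= vp.es_max
        assert vp.ea >= 0
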