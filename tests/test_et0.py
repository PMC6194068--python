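import datetime as dt
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wheatwater import (
    DailyWeatherRecord,
    HargreavesParams,
    PTConfig,
    SiteMetadata,
    alpha_advectivity,
    equilibrium_evapotranspiration,
    et0_hargreaves,
    et0_penman_monteith,
    et0_priestley_taylor,
)
from wheatwater.et0 import PMDailyInputs, et0_penman_monteith_from_inputs

from fao56_reference import reference_et0


class TestAlphaAdvectivity:
    @pytest.mark.parametrize("tmax", [5.0, 12.0, 20.0, 35.0])
    def test_temperate_band_is_constant(self, tmax):
        assert alpha_advectivity(tmax) == 1.1

    def test_cold_branch(self):
        assert alpha_advectivity(0.0) == pytest.approx(0.01 * math.e**3.6)

    def test_hot_branch(self):
        assert alpha_advectivity(40.0) == pytest.approx(1.35)

    def test_continuous_at_upper_boundary(self):
        assert alpha_advectivity(35.0 + 1e-9) == pytest.approx(1.1, abs=1e-7)

    def test_documented_jump_at_cold_boundary(self):
        # the cold branch does not meet 1.1 at 5 degC; the jump is a
        # property of the published piecewise definition
        jump = 1.1 - alpha_advectivity(5.0 - 1e-12)
        assert jump == pytest.approx(1.1 - 0.01 * math.exp(4.5), abs=1e-6)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            alpha_advectivity(float("nan"))

    @given(tmax=st.floats(-40.0, 50.0))
    @settings(max_examples=200, derandomize=True)
    def test_piecewise_definition(self, tmax):
        a = alpha_advectivity(tmax)
        if tmax < 5.0:
            assert a == pytest.approx(0.01 * math.exp(0.18 * (tmax + 20.0)))
        elif tmax <= 35.0:
            assert a == 1.1
        else:
            assert a == pytest.approx(1.1 + 0.05 * (tmax - 35.0))


class TestEquilibriumET:
    def test_zero_radiation_gives_zero(self):
        assert equilibrium_evapotranspiration(0.0, 30.0, 15.0) == 0.0

    def test_worked_value_zero_albedo(self):
        # SR=20, Tmax=Tmin=21 -> temperature factor 50
        v = equilibrium_evapotranspiration(20.0, 21.0, 21.0, PTConfig(albedo=0.0))
        assert v == pytest.approx(20.0 * 2.04e-4 * 50.0, rel=1e-12)

    def test_decreasing_in_albedo(self):
        vals = [
            equilibrium_evapotranspiration(20.0, 25.0, 10.0, PTConfig(albedo=a))
            for a in (0.0, 0.23, 0.5, 1.0)
        ]
        assert all(x > y for x, y in zip(vals, vals[1:]))

    def test_bad_albedo_rejected(self):
        with pytest.raises(ValueError):
            PTConfig(albedo=1.2)


class TestPriestleyTaylor:
    def _rec(self, srad, tmax=20.0, tmin=10.0):
        return DailyWeatherRecord(dt.date(2016, 4, 1), tmax, tmin, solar_rad=srad)

    def test_temperate_band_scales_eeq_by_11(self):
        rec = self._rec(20.0)
        eeq = equilibrium_evapotranspiration(20.0, 20.0, 10.0, PTConfig())
        assert et0_priestley_taylor(rec) == pytest.approx(1.1 * eeq)

    def test_zero_radiation_gives_zero(self):
        assert et0_priestley_taylor(self._rec(0.0, tmax=45.0, tmin=30.0)) == 0.0

    def test_missing_radiation_directs_to_angstrom_fill(self):
        rec = DailyWeatherRecord(dt.date(2016, 4, 1), 20.0, 10.0)
        with pytest.raises(ValueError, match="Angstrom"):
            et0_priestley_taylor(rec)

    def test_composition_over_season(self, season_weather_srad):
        # the composed operation must equal alpha * EEQ day by day
        cfg = PTConfig()
        for rec in season_weather_srad[:100]:
            expected = max(
                0.0,
                alpha_advectivity(rec.tmax)
                * equilibrium_evapotranspiration(rec.solar_rad, rec.tmax,
                                                 rec.tmin, cfg),
            )
            assert et0_priestley_taylor(rec, cfg) == pytest.approx(expected)


class TestPenmanMonteith:
    def test_zero_energy_zero_deficit_gives_zero(self):
        inp = PMDailyInputs(
            net_radiation=2.0, soil_heat_flux=2.0, tmean=16.9, u2=2.0,
            es=1.9, ea=1.9, slope=0.122, gamma=0.066,
        )
        assert et0_penman_monteith_from_inputs(inp) == 0.0

    def test_nondecreasing_in_vapor_deficit(self):
        vals = [
            et0_penman_monteith_from_inputs(
                PMDailyInputs(13.3, 0.0, 16.9, 2.08, 1.997, 1.997 - d,
                              0.122, 0.0666)
            )
            for d in (0.0, 0.3, 0.6, 0.9)
        ]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_missing_humidity_or_wind_rejected(self, site):
        rec = DailyWeatherRecord(dt.date(2016, 4, 1), 20.0, 10.0, solar_rad=20.0)
        with pytest.raises(ValueError, match="humidity"):
            et0_penman_monteith(rec, site)

    def test_matches_independent_fao56_reference(self):
        """1000 random admissible days against a separately written FAO-56
        daily transliteration, to 0.01 mm/d."""
        rng = np.random.default_rng(2016)
        worst = 0.0
        for _ in range(1000):
            doy = int(rng.integers(1, 366))
            lat = float(rng.uniform(-60, 60))
            elev = float(rng.uniform(0, 3000))
            tmin = float(rng.uniform(-15, 25))
            tmax = tmin + float(rng.uniform(0.5, 18))
            rh = float(rng.uniform(20, 100))
            u2 = float(rng.uniform(0.1, 8))
            rs = float(rng.uniform(1, 30))
            date = dt.date(2015, 1, 1) + dt.timedelta(days=doy - 1)
            rec = DailyWeatherRecord(date, tmax, tmin, rh_mean=rh, wind_2m=u2,
                                     solar_rad=rs)
            site = SiteMetadata("RND", latitude=lat, elevation=elev)
            ours = et0_penman_monteith(rec, site)
            ref = reference_et0(doy, lat, elev, tmax, tmin, rh, u2, rs)
            worst = max(worst, abs(ours - ref))
        assert worst <= 0.01


class TestHargreaves:
    def test_zero_diurnal_range_gives_zero(self):
        assert et0_hargreaves(15.0, 15.0, 30.0) == 0.0

    def test_worked_value_at_suggested_parameters(self):
        v = et0_hargreaves(30.0, 20.0, 40.0)
        expected = 0.0023 / 2.45 * math.sqrt(10.0) * (25.0 + 17.8) * 40.0
        assert v == pytest.approx(expected, rel=1e-12)
        assert v == pytest.approx(5.082, abs=5e-4)

    def test_zero_ra_gives_zero(self):
        assert et0_hargreaves(30.0, 20.0, 0.0) == 0.0

    def test_strict_printed_sum_variant(self):
        v = et0_hargreaves(30.0, 20.0, 40.0, strict_printed_sum=True)
        expected = 0.0023 / 2.45 * 50.0**0.5 * (25.0 + 17.8) * 40.0
        assert v == pytest.approx(expected, rel=1e-12)

    def test_cold_day_floored_at_zero(self):
        # mean temperature below -Toff turns the printed product negative
        assert et0_hargreaves(-20.0, -30.0, 10.0) == 0.0

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            et0_hargreaves(10.0, 20.0, 30.0)

    @given(
        tmin=st.floats(-5.0, 25.0),
        drange=st.floats(0.1, 20.0),
        ra=st.floats(0.1, 45.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_monotone_in_range_mean_and_ra(self, tmin, drange, ra):
        base = et0_hargreaves(tmin + drange, tmin, ra)
        assert et0_hargreaves(tmin + drange + 1.0, tmin, ra) > base
        assert et0_hargreaves(tmin + drange + 1.0, tmin + 1.0, ra) > base
        assert et0_hargreaves(tmin + drange, tmin, ra * 1.5) > base

    def test_parameter_invariants(self):
        with pytest.raises(ValueError):
            HargreavesParams(K=-0.001)
        with pytest.raises(ValueError):
            HargreavesParams(n_exp=1.6)
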