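"""REW, FAO-56 evapotranspiration, the daily bucket step, calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ringclim import synthetic_data
from ringclim.water_balance import (DegenerateSoilError, SitePhysio,
                                    SoilParams, calibrate, compute_rew,
                                    count_stress_days,
                                    penman_monteith_potential, simulate,
                                    slope_aspect_factor, step)


class TestREW:
    def test_boundary_values(self, soil):
        assert compute_rew(soil.theta_wp, soil) == 0.0
        assert compute_rew(soil.theta_hc, soil) == 1.0
        mid = (soil.theta_wp + soil.theta_hc) / 2
        assert compute_rew(mid, soil) == pytest.approx(0.5, rel=1e-12)

    def test_clamped_outside_physical_range(self, soil):
        assert compute_rew(0.0, soil) == 0.0
        assert compute_rew(1.0, soil) == 1.0

    def test_degenerate_soil_rejected(self):
        with pytest.raises((DegenerateSoilError, ValueError)):
            SoilParams(theta_wp=0.2, theta_hc=0.2)


class TestStressDays:
    def test_counts(self):
        rew = [0.3, 0.5, 0.8]
        assert count_stress_days(rew, 0.4) == 1
        assert count_stress_days(rew, 0.7) == 2
        assert count_stress_days(np.ones(100), 0.4) == 0

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        rew = rng.random(500)
        assert count_stress_days(rew, 0.4) <= count_stress_days(rew, 0.7)

    def test_strict_vs_inclusive(self):
        rew = [0.4, 0.39, 0.41]
        assert count_stress_days(rew, 0.4, strict=True) == 1
        assert count_stress_days(rew, 0.4, strict=False) == 2


def _fao56_oracle(tmin, tmax, rh, rs, wind, elev, lat, doy):
    """Second, literal transcription of the FAO-56 ET0 computation."""
    tmean = (tmin + tmax) / 2
    e0 = lambda t: 0.6108 * np.exp(17.27 * t / (t + 237.3))  # noqa: E731
    es = (e0(tmin) + e0(tmax)) / 2
    ea = rh * es
    slope = 4098 * e0(tmean) / (tmean + 237.3) ** 2
    P = 101.3 * ((293 - 0.0065 * elev) / 293) ** 5.26
    gam = 0.000665 * P
    phi = np.deg2rad(lat)
    dr = 1 + 0.033 * np.cos(2 * np.pi / 365 * doy)
    dec = 0.409 * np.sin(2 * np.pi / 365 * doy - 1.39)
    ws = np.arccos(-np.tan(phi) * np.tan(dec))
    ra = 24 * 60 / np.pi * 0.0820 * dr * (
        ws * np.sin(phi) * np.sin(dec)
        + np.cos(phi) * np.cos(dec) * np.sin(ws))
    rso = (0.75 + 2e-5 * elev) * ra
    rns = 0.77 * rs
    rnl = (4.903e-9 * ((tmax + 273.16) ** 4 + (tmin + 273.16) ** 4) / 2
           * (0.34 - 0.14 * np.sqrt(ea)) * (1.35 * rs / rso - 0.35))
    rn = rns - rnl
    return (0.408 * slope * rn
            + gam * 900 / (tmean + 273) * wind * (es - ea)) / (
        slope + gam * (1 + 0.34 * wind))


class TestPenmanMonteith:
    def test_no_demand_when_saturated_dark_calm(self):
        day = {"date": "2005-06-21", "tmin": 10.0, "tmax": 10.0,
               "tmean": 10.0, "rh": 1.0, "global_rad": 0.0, "wind": 0.0}
        assert penman_monteith_potential(day, 500, 48.12) <= 0.05

    def test_increases_with_vapour_pressure_deficit(self):
        base = {"date": "2005-06-21", "tmin": 12.0, "tmax": 24.0,
                "tmean": 18.0, "rh": 0.8, "global_rad": 22.0, "wind": 2.0}
        drier = {**base, "rh": 0.4}
        assert (penman_monteith_potential(drier, 500, 48.12)
                > penman_monteith_potential(base, 500, 48.12))

    def test_matches_independent_fao56_transcription(self):
        # a standard mid-latitude summer day
        day = {"date": "2005-07-06", "tmin": 12.3, "tmax": 21.5,
               "tmean": 16.9, "rh": 0.63, "global_rad": 22.07, "wind": 2.78}
        doy = pd.Timestamp("2005-07-06").dayofyear
        oracle = _fao56_oracle(12.3, 21.5, 0.63, 22.07, 2.78, 100.0, 50.8,
                               doy)
        got = penman_monteith_potential(day, 100.0, 50.8)
        assert got == pytest.approx(oracle, rel=1e-3)

    def test_rh_out_of_range_rejected(self):
        day = {"date": "2005-07-06", "tmin": 12.0, "tmax": 22.0,
               "tmean": 17.0, "rh": 63.0, "global_rad": 22.0, "wind": 2.0}
        with pytest.raises(ValueError, match="rh"):
            penman_monteith_potential(day, 100.0, 50.8)


class TestSlopeAspect:
    def test_horizontal_identity(self):
        p = SitePhysio("s", 48.0, slope=0.0, aspect=123.0)
        assert slope_aspect_factor("2005-12-21", p) == 1.0

    def test_north_slope_winter_below_one(self):
        p = SitePhysio("s", 48.0, slope=30.0, aspect=0.0)
        assert slope_aspect_factor("2005-12-21", p) < 1.0

    def test_south_slope_winter_above_one(self):
        p = SitePhysio("s", 48.0, slope=30.0, aspect=180.0)
        assert slope_aspect_factor("2005-12-21", p) > 1.0

    def test_invalid_physiography_rejected(self):
        with pytest.raises(ValueError):
            SitePhysio("s", 48.0, slope=95.0)
        with pytest.raises(ValueError):
            SitePhysio("s", 48.0, aspect=400.0)


class TestStep:
    def _day(self, **kw):
        base = {"date": pd.Timestamp("2005-06-21"), "tmin": 10.0,
                "tmax": 20.0, "tmean": 15.0, "precip": 0.0, "rh": 0.6,
                "global_rad": 20.0, "wind": 2.0}
        base.update(kw)
        return base

    def test_dry_soil_shuts_transpiration(self, soil):
        rec, (theta, _) = step(self._day(), (soil.theta_wp, 0.0), soil,
                               in_leaf=True)
        assert rec.t_act == 0.0
        assert theta == pytest.approx(soil.theta_wp, abs=1e-12)

    def test_saturated_soil_drains_all_throughfall(self, soil):
        rec, _ = step(self._day(precip=50.0, global_rad=0.0, wind=0.0,
                                rh=1.0),
                      (soil.theta_hc, 0.0), soil, in_leaf=True)
        assert rec.drainage == pytest.approx(
            rec.throughfall - rec.t_act, abs=1e-12)

    def test_no_reduction_at_rew_crit(self, soil):
        theta = soil.theta_wp + soil.rew_crit * (soil.theta_hc
                                                 - soil.theta_wp)
        rec, _ = step(self._day(), (theta, 0.0), soil, in_leaf=True)
        assert rec.t_act == pytest.approx(rec.t_pot, rel=1e-12)

    def test_snow_partition_and_melt(self, soil):
        cold, state = step(self._day(tmean=-5.0, tmin=-8.0, tmax=-2.0,
                                     precip=10.0),
                           (0.3, 0.0), soil, in_leaf=False)
        assert cold.snowfall == 10.0 and cold.rain == 0.0
        assert state[1] == 10.0
        warm, state2 = step(self._day(tmean=2.0, tmin=-1.0, tmax=5.0),
                            state, soil, in_leaf=False)
        assert warm.melt == pytest.approx(
            min(10.0, soil.snow_melt_factor * 2.0))


class TestMassBalance:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_daily_closure_under_random_forcing(self, seed, soil):
        rng = np.random.default_rng(seed)
        n = 200
        dates = pd.date_range("2005-01-01", periods=n, freq="D")
        tmean = rng.uniform(-15, 30, n)
        wx = pd.DataFrame({
            "date": dates, "tmean": tmean, "tmin": tmean - 5,
            "tmax": tmean + 5,
            "precip": rng.exponential(4.0, n) * (rng.random(n) < 0.5),
            "rh": rng.uniform(0.3, 1.0, n),
            "global_rad": rng.uniform(0, 30, n),
            "wind": rng.uniform(0, 8, n),
        })
        leaf = rng.random(n) < 0.5
        theta0 = rng.uniform(soil.theta_wp, soil.theta_hc)
        res = simulate(wx, soil, in_leaf=leaf, theta0=theta0)
        theta = res["theta"].to_numpy()
        theta_prev = np.concatenate([[theta0], theta[:-1]])
        lhs = (res["rain"] + res["melt"] - res["interception"]
               - res["t_act"] - res["drainage"]).to_numpy()
        dstorage = (theta - theta_prev) * soil.root_depth
        assert np.max(np.abs(lhs - dstorage)) < 1e-9

    def test_state_bounds(self, decade_weather, soil):
        res = simulate(decade_weather, soil)
        assert (res["theta"] >= soil.theta_wp - 1e-12).all()
        assert (res["theta"] <= soil.theta_hc + 1e-12).all()
        assert ((res["rew"] >= 0) & (res["rew"] <= 1)).all()
        assert (res["t_act"] <= res["t_pot"] + 1e-12).all()
        assert (res["t_deficit"] >= -1e-12).all()

    def test_warming_never_decreases_annual_potential_transpiration(
            self, decade_weather, soil):
        base = simulate(decade_weather, soil)
        warm_wx = decade_weather.assign(
            tmean=decade_weather["tmean"] + 3.0,
            tmin=decade_weather["tmin"] + 3.0,
            tmax=decade_weather["tmax"] + 3.0)
        warm = simulate(warm_wx, soil)
        years = pd.DatetimeIndex(decade_weather["date"]).year
        base_ann = base.groupby(years)["t_pot"].sum()
        warm_ann = warm.groupby(years)["t_pot"].sum()
        assert (warm_ann >= base_ann - 1e-9).all()


class TestCalibration:
    def test_noise_free_self_consistency(self, decade_weather):
        truth = SoilParams()
        obs = synthetic_data.generate_soil_moisture_obs(
            decade_weather, truth, noise_sd=0.0)
        sim = simulate(decade_weather, truth)
        np.testing.assert_allclose(obs["theta"], sim["theta"], atol=1e-12)
        fitted, rmse, _ = calibrate(
            decade_weather, obs,
            bounds={"theta_hc": (0.25, 0.45),
                    "root_depth": (400.0, 1200.0)},
            n_starts=4, seed=1)
        assert rmse < 1e-6

    def test_theta_hc_recovery_under_noise(self, decade_weather):
        truth = SoilParams()
        wx = decade_weather[pd.DatetimeIndex(decade_weather["date"]).year
                            <= 2005].reset_index(drop=True)
        recovered = []
        for rep in range(20):
            obs = synthetic_data.generate_soil_moisture_obs(
                wx, truth, noise_sd=0.02, seed=rep)
            fitted, _, _ = calibrate(
                wx, obs, bounds={"theta_hc": (0.25, 0.45)},
                n_starts=2, seed=2)
            recovered.append(fitted.theta_hc)
        assert abs(np.mean(recovered) - truth.theta_hc) / truth.theta_hc \
            < 0.10

    def test_bounds_excluding_truth_flagged(self, decade_weather):
        truth = SoilParams()
        obs = synthetic_data.generate_soil_moisture_obs(
            decade_weather, truth, noise_sd=0.0)
        fitted, _, on_boundary = calibrate(
            decade_weather, obs,
            bounds={"theta_hc": (0.40, 0.45)}, n_starts=3, seed=3)
        assert on_boundary
        assert fitted.theta_hc == pytest.approx(0.40, abs=1e-6)

    def test_insufficient_overlap_rejected(self, one_year_weather):
        obs = pd.DataFrame({"date": pd.date_range("1990-01-01", periods=30),
                            "theta": 0.3})
        with pytest.raises(ValueError, match="overlap"):
            calibrate(one_year_weather, obs,
                      bounds={"theta_hc": (0.25, 0.45)})
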