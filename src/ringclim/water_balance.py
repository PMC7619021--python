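"""Daily single-store forest water balance.

A one-bucket soil store of depth ``root_depth`` holds volumetric water
content between the wilting point (theta_wp) and the water-holding
capacity (theta_hc).  Each day, in fixed order: precipitation is
partitioned into rain or snow, snowmelt is released, throughfall (rain
net of canopy interception, plus melt) enters the store, potential
transpiration is taken from FAO-56 reference evapotranspiration gated
by leaf phenology, actual transpiration is reduced linearly below a
relative-extractable-water threshold, and water above capacity drains.

Relative extractable water (REW) rescales soil moisture to 0 at the
wilting point and 1 at holding capacity; REW < 0.4 marks severe and
REW < 0.7 (at least) mild water stress.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc

from ._solar import extraterrestrial_radiation

STEFAN_BOLTZMANN = 4.903e-9  # MJ K-4 m-2 day-1


class DegenerateSoilError(ValueError):
    """theta_hc equals theta_wp: REW undefined."""


@dataclass(frozen=True)
class SoilParams:
    """Soil and canopy parameters of the bucket model.

    theta_wp / theta_hc are volumetric fractions; ``root_depth`` (mm)
    converts volumetric content to a water column.  ``rew_crit`` is the
    REW breakpoint below which transpiration is reduced linearly
    (Granier-type closure, default 0.4 = the severe-stress onset).
    """

    theta_wp: float = 0.15
    theta_hc: float = 0.35
    root_depth: float = 800.0          # mm
    rew_crit: float = 0.4
    interception_frac: float = 0.15    # of in-leaf rain
    snow_melt_factor: float = 3.0      # mm degC-1 day-1
    canopy_coef: float = 0.85          # t_pot = canopy_coef * ET0 in leaf
    dormant_transp_coef: float = 0.0   # gate outside the growing season

    def __post_init__(self):
        if not 0.0 <= self.theta_wp < self.theta_hc <= 1.0:
            if self.theta_wp == self.theta_hc:
                raise DegenerateSoilError(
                    "theta_hc must exceed theta_wp"
                )
            raise ValueError("need 0 <= theta_wp < theta_hc <= 1")
        if self.root_depth <= 0:
            raise ValueError("root_depth must be positive")
        if not 0.0 < self.rew_crit <= 1.0:
            raise ValueError("rew_crit must be in (0, 1]")


@dataclass(frozen=True)
class SitePhysio:
    """Site physiography used for the radiation adjustment."""

    site_id: str
    latitude: float
    elevation: float = 500.0
    slope: float = 0.0     # degrees
    aspect: float = 0.0    # degrees clockwise from north

    def __post_init__(self):
        if not 0.0 <= self.slope < 90.0:
            raise ValueError("slope must be in [0, 90)")
        if not 0.0 <= self.aspect < 360.0:
            raise ValueError("aspect must be in [0, 360)")


def compute_rew(theta, soil: SoilParams):
    """Relative extractable water, clamped to [0, 1].

    REW = (theta - theta_wp) / (theta_hc - theta_wp).
    """
    span = soil.theta_hc - soil.theta_wp
    if span <= 0:
        raise DegenerateSoilError("theta_hc must exceed theta_wp")
    return np.clip((np.asarray(theta, dtype=float) - soil.theta_wp) / span,
                   0.0, 1.0)


def count_stress_days(rew, threshold: float, strict: bool = True) -> int:
    """Number of days with REW below the threshold.

    Strict "<" by default; set ``strict=False`` for "<=".
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    rew = np.asarray(rew, dtype=float)
    return int((rew < threshold).sum() if strict else (rew <= threshold).sum())


# ---------------------------------------------------------------------------
# FAO-56 reference evapotranspiration
# ---------------------------------------------------------------------------

def _saturation_vp(t):
    """Saturation vapour pressure (kPa) at air temperature t (degC)."""
    return 0.6108 * np.exp(17.27 * t / (t + 237.3))


def penman_monteith_potential(day, elevation: float, latitude: float):
    """FAO-56 reference evapotranspiration ET0 in mm/day.

    ``day`` is a daily weather record (mapping or DataFrame row/frame
    with tmin, tmax, tmean, rh, global_rad, wind, date).  Vectorised
    when passed a DataFrame.  Soil heat flux is taken as zero at the
    daily step; actual vapour pressure is rh times the mean saturation
    vapour pressure at tmin/tmax.
    """
    if isinstance(day, pd.DataFrame):
        get = lambda k: day[k].to_numpy(dtype=float)  # noqa: E731
        dates = pd.DatetimeIndex(day["date"])
    else:
        get = lambda k: np.asarray(day[k], dtype=float)  # noqa: E731
        dates = pd.DatetimeIndex(np.atleast_1d(pd.to_datetime(day["date"])))
    tmin, tmax, tmean = get("tmin"), get("tmax"), get("tmean")
    rh, rs, wind = get("rh"), get("global_rad"), get("wind")
    if np.any((rh < 0) | (rh > 1)):
        raise ValueError("rh outside [0, 1]")

    es = (_saturation_vp(tmin) + _saturation_vp(tmax)) / 2.0
    ea = rh * es
    delta = (4098.0 * _saturation_vp(tmean)) / (tmean + 237.3) ** 2
    pressure = 101.3 * ((293.0 - 0.0065 * elevation) / 293.0) ** 5.26
    gamma = 0.000665 * pressure

    doy = dates.dayofyear.to_numpy()
    ra = extraterrestrial_radiation(latitude, doy)
    rso = (0.75 + 2e-5 * elevation) * ra
    rns = (1.0 - 0.23) * rs
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(rso > 0, np.clip(rs / np.where(rso > 0, rso, 1.0),
                                        0.0, 1.0), 0.0)
    tk4 = ((tmax + 273.16) ** 4 + (tmin + 273.16) ** 4) / 2.0
    # net longwave is a loss term; floored at 0 where the cloudiness
    # function extrapolates negative (overcast, zero shortwave)
    rnl = np.maximum(
        STEFAN_BOLTZMANN * tk4
        * (0.34 - 0.14 * np.sqrt(np.maximum(ea, 0.0)))
        * (1.35 * rel - 0.35),
        0.0)
    rn = rns - rnl

    num = (0.408 * delta * rn
           + gamma * 900.0 / (tmean + 273.0) * wind * (es - ea))
    den = delta + gamma * (1.0 + 0.34 * wind)
    et0 = np.maximum(num / den, 0.0)
    return et0 if et0.size > 1 else float(et0[0])


# ---------------------------------------------------------------------------
# Slope/aspect radiation adjustment
# ---------------------------------------------------------------------------

def slope_aspect_factor(date, physio: SitePhysio, step_minutes: float = 1.0):
    """Ratio of daily direct-beam irradiance on the tilted plane to the
    horizontal plane, by minute-stepped integration of solar geometry.

    The factor multiplies the direct fraction of global radiation only.
    Returns 1.0 for a horizontal surface; can exceed 1 for sun-facing
    slopes in winter.  If the sun never rises, returns 1.0 (no beam to
    adjust).
    """
    if physio.slope == 0.0:
        return 1.0
    doy = pd.Timestamp(date).dayofyear
    phi = np.deg2rad(physio.latitude)
    delta = 0.409 * np.sin(2.0 * np.pi * doy / 365.0 - 1.39)
    beta = np.deg2rad(physio.slope)
    gamma = np.deg2rad(physio.aspect)

    # hour angle grid over the full day
    minutes = np.arange(0.0, 24.0 * 60.0, step_minutes) + step_minutes / 2.0
    omega = np.deg2rad((minutes / 60.0 - 12.0) * 15.0)

    cos_z = (np.sin(phi) * np.sin(delta)
             + np.cos(phi) * np.cos(delta) * np.cos(omega))
    sin_z = np.sqrt(np.clip(1.0 - cos_z ** 2, 0.0, None))
    # solar azimuth measured clockwise from north
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_az = np.where(sin_z > 1e-12,
                          (np.sin(delta) - np.sin(phi) * cos_z)
                          / (np.cos(phi) * np.where(sin_z > 1e-12, sin_z, 1.0)),
                          1.0)
    az = np.arccos(np.clip(cos_az, -1.0, 1.0))
    az = np.where(omega > 0, 2.0 * np.pi - az, az)

    cos_inc = (cos_z * np.cos(beta)
               + sin_z * np.sin(beta) * np.cos(az - gamma))
    up = cos_z > 0
    horiz = np.sum(np.where(up, cos_z, 0.0))
    tilted = np.sum(np.where(up, np.maximum(cos_inc, 0.0), 0.0))
    if horiz <= 0:
        return 1.0
    return float(tilted / horiz)


def adjust_radiation(rs, date, physio: SitePhysio,
                     diffuse_frac: float = 0.3):
    """Apply the slope/aspect factor to the direct fraction of global
    radiation; the diffuse fraction (default 0.3) is left isotropic."""
    f = slope_aspect_factor(date, physio)
    return rs * (diffuse_frac + (1.0 - diffuse_frac) * f)


# ---------------------------------------------------------------------------
# Daily step and simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaterBalanceDay:
    """State and fluxes of one simulated day (mm water column unless
    volumetric)."""

    date: object
    theta: float
    rew: float
    t_pot: float
    t_act: float
    t_deficit: float
    drainage: float
    snowpack: float
    in_leaf: bool
    rain: float
    snowfall: float
    melt: float
    interception: float
    throughfall: float
    et0: float


def step(day, state: tuple[float, float], soil: SoilParams, in_leaf: bool,
         et0: float | None = None, elevation: float = 500.0,
         latitude: float = 48.0) -> tuple[WaterBalanceDay, tuple[float, float]]:
    """Advance the bucket one day.

    ``state`` is (theta, snowpack_mm).  Flux order: precipitation
    partition, melt, throughfall, potential transpiration, actual
    transpiration (linear REW reduction), storage update, drainage.
    Returns the day's record and the new state.
    """
    theta, snowpack = state
    tmean = float(day["tmean"])
    precip = float(day["precip"])
    if et0 is None:
        et0 = penman_monteith_potential(day, elevation, latitude)

    snowfall = precip if tmean < 0.0 else 0.0
    rain = precip - snowfall
    snowpack += snowfall
    melt = min(snowpack, soil.snow_melt_factor * max(tmean, 0.0))
    snowpack -= melt

    interception = rain * soil.interception_frac * (1.0 if in_leaf else 0.0)
    throughfall = rain - interception + melt

    gate = soil.canopy_coef if in_leaf else soil.dormant_transp_coef
    t_pot = gate * et0
    rew = float(compute_rew(theta, soil))
    t_act = t_pot * min(1.0, rew / soil.rew_crit)
    # cannot extract below the wilting point
    t_act = min(t_act, (theta - soil.theta_wp) * soil.root_depth + throughfall)

    storage = theta * soil.root_depth + throughfall - t_act
    capacity = soil.theta_hc * soil.root_depth
    drainage = max(0.0, storage - capacity)
    storage -= drainage
    theta_new = storage / soil.root_depth

    rec = WaterBalanceDay(
        date=day["date"], theta=theta_new,
        rew=float(compute_rew(theta_new, soil)),
        t_pot=t_pot, t_act=t_act, t_deficit=t_pot - t_act,
        drainage=drainage, snowpack=snowpack, in_leaf=bool(in_leaf),
        rain=rain, snowfall=snowfall, melt=melt,
        interception=interception, throughfall=throughfall, et0=float(et0),
    )
    return rec, (theta_new, snowpack)


def simulate(weather: pd.DataFrame, soil: SoilParams,
             physio: SitePhysio | None = None,
             in_leaf: np.ndarray | None = None,
             theta0: float | None = None,
             elevation: float | None = None,
             latitude: float | None = None) -> pd.DataFrame:
    """Run the bucket model over a daily weather table.

    ``in_leaf`` is a per-day boolean growing-season gate (default all
    in leaf).  ET0 is vectorised up-front; if ``physio`` has a nonzero
    slope the direct radiation fraction is tilted first.  Returns a
    DataFrame of daily states and fluxes.
    """
    if physio is not None:
        elevation = physio.elevation if elevation is None else elevation
        latitude = physio.latitude if latitude is None else latitude
    elevation = 500.0 if elevation is None else elevation
    latitude = 48.0 if latitude is None else latitude

    wx = weather.reset_index(drop=True)
    if physio is not None and physio.slope > 0.0:
        wx = wx.copy()
        dates = pd.DatetimeIndex(wx["date"])
        # factor depends only on day-of-year; compute each doy once
        factors = {d: slope_aspect_factor(pd.Timestamp(2001, 1, 1)
                                          + pd.Timedelta(days=int(d) - 1),
                                          physio)
                   for d in np.unique(dates.dayofyear)}
        f = np.array([factors[d] for d in dates.dayofyear])
        diffuse = 0.3
        wx["global_rad"] = (wx["global_rad"].to_numpy()
                            * (diffuse + (1.0 - diffuse) * f))

    et0 = np.atleast_1d(penman_monteith_potential(wx, elevation, latitude))
    if in_leaf is None:
        in_leaf = np.ones(len(wx), dtype=bool)
    in_leaf = np.asarray(in_leaf, dtype=bool)
    theta = soil.theta_hc if theta0 is None else float(theta0)
    state = (theta, 0.0)

    tmean = wx["tmean"].to_numpy(dtype=float)
    precip = wx["precip"].to_numpy(dtype=float)
    dates = wx["date"].to_numpy()

    n = len(wx)
    out = np.empty((n, 13))
    rd = soil.root_depth
    cap = soil.theta_hc * rd
    wp = soil.theta_wp
    span = soil.theta_hc - wp
    theta, snowpack = state
    for i in range(n):
        tm = tmean[i]
        pr = precip[i]
        leafy = in_leaf[i]
        snowfall = pr if tm < 0.0 else 0.0
        rain = pr - snowfall
        snowpack += snowfall
        melt = soil.snow_melt_factor * tm if tm > 0.0 else 0.0
        if melt > snowpack:
            melt = snowpack
        snowpack -= melt
        interception = rain * soil.interception_frac if leafy else 0.0
        throughfall = rain - interception + melt
        gate = soil.canopy_coef if leafy else soil.dormant_transp_coef
        t_pot = gate * et0[i]
        rew = (theta - wp) / span
        if rew < 0.0:
            rew = 0.0
        elif rew > 1.0:
            rew = 1.0
        red = rew / soil.rew_crit
        t_act = t_pot * (red if red < 1.0 else 1.0)
        avail = (theta - wp) * rd + throughfall
        if t_act > avail:
            t_act = avail
        storage = theta * rd + throughfall - t_act
        drainage = storage - cap
        if drainage < 0.0:
            drainage = 0.0
        storage -= drainage
        theta = storage / rd
        rew_new = (theta - wp) / span
        if rew_new < 0.0:
            rew_new = 0.0
        elif rew_new > 1.0:
            rew_new = 1.0
        out[i] = (theta, rew_new, t_pot, t_act, t_pot - t_act, drainage,
                  snowpack, rain, snowfall, melt, interception, throughfall,
                  et0[i])

    res = pd.DataFrame(out, columns=[
        "theta", "rew", "t_pot", "t_act", "t_deficit", "drainage",
        "snowpack", "rain", "snowfall", "melt", "interception",
        "throughfall", "et0",
    ])
    res.insert(0, "date", dates)
    res["in_leaf"] = in_leaf
    return res


def write_wbm_csv(result: pd.DataFrame, path) -> None:
    cols = {"theta": "theta", "rew": "rew", "t_pot": "t_pot_mm",
            "t_act": "t_act_mm", "t_deficit": "deficit_mm",
            "drainage": "drainage_mm", "snowpack": "snow_mm"}
    out = result[["date", *cols]].rename(columns=cols).copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def calibrate(
    weather: pd.DataFrame,
    observed_theta: pd.DataFrame,
    bounds: dict[str, tuple[float, float]],
    base: SoilParams | None = None,
    in_leaf: np.ndarray | None = None,
    elevation: float = 500.0,
    latitude: float = 48.0,
    n_starts: int = 8,
    seed: int = 0,
) -> tuple[SoilParams, float, bool]:
    """Fit soil parameters to an observed soil-moisture series.

    Minimises the RMSE between simulated and observed volumetric soil
    moisture (matched on date) over the parameters named in ``bounds``,
    by bounded local search (L-BFGS-B) from a Latin-hypercube
    multistart with a fixed seed.  Returns (params, rmse,
    on_boundary); ``on_boundary`` flags a solution pinned to a bound.
    """
    base = base or SoilParams()
    obs = observed_theta.copy()
    obs["date"] = pd.to_datetime(obs["date"])
    wx = weather.copy()
    wx["date"] = pd.to_datetime(wx["date"])
    mask = wx["date"].isin(set(obs["date"]))
    if int(mask.sum()) < 365:
        raise ValueError("overlap of weather and observations < 1 year")
    obs = obs.set_index("date").loc[wx.loc[mask, "date"], "theta"].to_numpy()

    names = list(bounds)
    lo = np.array([bounds[k][0] for k in names])
    hi = np.array([bounds[k][1] for k in names])

    def build(x) -> SoilParams:
        return replace(base, **dict(zip(names, x)))

    def loss(x):
        try:
            p = build(x)
        except (ValueError, DegenerateSoilError):
            return 1e6
        sim = simulate(wx, p, in_leaf=in_leaf, elevation=elevation,
                       latitude=latitude)
        return float(np.sqrt(np.mean(
            (sim.loc[mask.to_numpy(), "theta"].to_numpy() - obs) ** 2)))

    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    starts = lo + sampler.random(n_starts) * (hi - lo)
    best = (np.inf, None)
    for x0 in starts:
        res = optimize.minimize(loss, x0, method="L-BFGS-B",
                                bounds=list(zip(lo, hi)),
                                options={"maxiter": 60})
        if res.fun < best[0]:
            best = (res.fun, res.x)
    # derivative-free polish: the loss has clipping kinks that blunt
    # finite-difference gradients near the optimum
    polish = optimize.minimize(
        loss, best[1], method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-12, "maxfev": 400})
    x = np.clip(polish.x, lo, hi)
    rmse = loss(x)
    if rmse > best[0]:
        rmse, x = best
    on_boundary = bool(np.any(np.isclose(x, lo, atol=1e-9) |
                              np.isclose(x, hi, atol=1e-9)))
    return build(x), float(rmse), on_boundary
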