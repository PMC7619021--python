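"""Synthetic inputs with known ground truth for every pipeline stage.

No site data are deposited for the study system this package targets,
so all inputs are emulated: seasonally cyclic daily weather with
stochastic precipitation, soil-moisture "observations" produced by a
known water-balance parameterisation plus noise, phenological events
with interannual plasticity, and ring-width series composed of a known
age curve, a linear combination of standardised growth factors, site
random intercepts and residual noise.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .age_detrend import AgeCurveParams, age_curve
from .phenology import NO_EVENT, PhenoParams, predict_growing_season
from .water_balance import SoilParams, simulate

log = logging.getLogger(__name__)

#: Wet-day probability per season block (temperate mid-latitude values).
DEFAULT_WET_PROB = {"Jan-Mar": 0.40, "Apr-May": 0.42, "Jun-Jul": 0.45,
                    "Aug-Sep": 0.40, "Oct-Dec": 0.40}


@dataclass(frozen=True)
class WeatherGenConfig:
    """Configuration of the daily weather generator.

    Temperature is a sinusoid peaking at day-of-year 200 plus iid
    Gaussian noise; tmin/tmax are tmean -/+ ``temp_half_range``.
    Precipitation occurrence is an independent per-season Bernoulli
    draw with Gamma-distributed amounts.  The sunshine fraction is
    Beta-distributed and anti-correlated with wet days.
    """

    site_id: str = "site-1"
    latitude: float = 48.12
    start_year: int = 2001
    end_year: int = 2020
    temp_mean_annual: float = 9.0        # degC
    temp_seasonal_amplitude: float = 10.0
    temp_daily_sd: float = 3.0
    temp_interannual_sd: float = 0.8     # per-calendar-year anomaly
    temp_half_range: float = 5.0
    precip_wet_prob_by_season: dict = field(
        default_factory=lambda: dict(DEFAULT_WET_PROB))
    precip_gamma_shape: float = 0.7
    precip_gamma_scale: float = 8.0      # mm
    rh_mean: float = 0.75
    rh_sd: float = 0.08
    wind_mean: float = 2.0               # m/s
    seed: int = 0

    def __post_init__(self):
        if self.end_year < self.start_year:
            raise ValueError("end_year must be >= start_year")
        for s, p in self.precip_wet_prob_by_season.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"wet probability for {s!r} outside [0,1]")
        if self.precip_gamma_shape <= 0 or self.precip_gamma_scale <= 0:
            raise ValueError("gamma parameters must be positive")


def generate_weather(cfg: WeatherGenConfig) -> pd.DataFrame:
    """One daily weather record per calendar day of the config window."""
    from .seasons import month_to_season  # local to avoid cycle at import

    rng = np.random.default_rng(cfg.seed)
    dates = pd.date_range(f"{cfg.start_year}-01-01",
                          f"{cfg.end_year}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy()
    n = len(dates)

    seasonal = cfg.temp_seasonal_amplitude * np.cos(
        2.0 * np.pi * (doy - 200) / 365.25)
    year_idx = dates.year.to_numpy() - cfg.start_year
    annual = rng.normal(0.0, cfg.temp_interannual_sd,
                        cfg.end_year - cfg.start_year + 1)
    tmean = (cfg.temp_mean_annual + seasonal + annual[year_idx]
             + rng.normal(0.0, cfg.temp_daily_sd, n))
    tmin = tmean - cfg.temp_half_range
    tmax = tmean + cfg.temp_half_range

    seasons = np.array([month_to_season(m) for m in dates.month])
    wet_p = np.array([cfg.precip_wet_prob_by_season.get(s, 0.0)
                      for s in seasons])
    wet = rng.random(n) < wet_p
    amounts = rng.gamma(cfg.precip_gamma_shape, cfg.precip_gamma_scale, n)
    precip = np.where(wet, amounts, 0.0)

    # wet days are cloudier: Beta(2,4) wet vs Beta(4,2) dry
    sun_wet = rng.beta(2.0, 4.0, n)
    sun_dry = rng.beta(4.0, 2.0, n)
    sunshine = np.where(wet, sun_wet, sun_dry)

    rh = np.clip(rng.normal(cfg.rh_mean, cfg.rh_sd, n)
                 + 0.05 * wet, 0.2, 1.0)
    wind = np.maximum(rng.gamma(4.0, cfg.wind_mean / 4.0, n), 0.1)

    return pd.DataFrame({
        "date": dates, "tmin": tmin, "tmax": tmax, "tmean": tmean,
        "precip": precip, "rh": rh, "sunshine_frac": sunshine,
        "wind": wind,
    })


def generate_soil_moisture_obs(weather: pd.DataFrame,
                               true_params: SoilParams,
                               noise_sd: float,
                               seed: int = 0,
                               in_leaf: np.ndarray | None = None,
                               elevation: float = 500.0,
                               latitude: float = 48.0) -> pd.DataFrame:
    """Noisy soil-moisture "observations" from a known parameterisation.

    Runs the bucket model under ``true_params`` and adds Gaussian noise
    of sd ``noise_sd`` (volumetric fraction), clipping to the physical
    range [theta_wp, theta_hc].  ``noise_sd=0`` returns the simulated
    trajectory exactly.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    sim = simulate(weather, true_params, in_leaf=in_leaf,
                   elevation=elevation, latitude=latitude)
    theta = sim["theta"].to_numpy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        theta = np.clip(theta + rng.normal(0.0, noise_sd, len(theta)),
                        true_params.theta_wp, true_params.theta_hc)
    return pd.DataFrame({"date": sim["date"], "theta": theta})


def generate_phenology_obs(weather: pd.DataFrame, latitude: float,
                           params: PhenoParams, noise_sd_days: float = 2.0,
                           seed: int = 0) -> pd.DataFrame:
    """Leaf-unfolding / leaf-coloring observations per year, with
    interannual plasticity from the weather plus observation noise."""
    rng = np.random.default_rng(seed)
    years = pd.DatetimeIndex(weather["date"]).year
    rows = []
    for year, sub in weather.groupby(years):
        lu, lc = predict_growing_season(sub, latitude, params)
        if lu == NO_EVENT:
            continue
        rows.append({"year": int(year), "event": "BBCH11",
                     "doy": int(round(lu + rng.normal(0, noise_sd_days)))})
        rows.append({"year": int(year), "event": "BBCH94",
                     "doy": int(round(lc + rng.normal(0, noise_sd_days)))})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RingGenTruth:
    """Ground-truth generative structure for ring-width series.

    ``beta`` maps (factor, season, lag) keys to effects in mm per SD
    unit of the standardised growth factor.  Each tree's observed width
    is the age curve plus the linear factor combination plus a site
    random intercept and iid residual noise.
    """

    age_params: AgeCurveParams
    beta: dict = field(default_factory=dict)
    site_intercept_sd: float = 0.15   # mm
    residual_sd: float = 0.25         # mm
    n_sites: int = 4
    trees_per_site: int = 7
    age_at_start_range: tuple[int, int] = (20, 140)
    species: str = "Fagus sylvatica"
    seed: int = 0

    def __post_init__(self):
        if self.trees_per_site <= 0 or self.n_sites <= 0:
            raise ValueError("n_sites and trees_per_site must be positive")
        if self.residual_sd < 0 or self.site_intercept_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")


def generate_ring_series(truth: RingGenTruth,
                         factors: pd.DataFrame) -> pd.DataFrame:
    """Ring-width series with known structure from standardised factors.

    ``factors`` is a long standardised table (site_id, growth_year,
    season, lag, factor, std_value) covering every (site, year) to be
    generated; sites are taken from it in sorted order (the first
    ``n_sites``).  Negative widths are floored at 0.01 mm and flagged
    in the ``floored`` column (count logged).
    """
    rng = np.random.default_rng(truth.seed)
    sites = sorted(factors["site_id"].unique())[: truth.n_sites]
    if len(sites) < truth.n_sites:
        raise ValueError(
            f"factors cover {len(sites)} site(s); need {truth.n_sites}"
        )
    years = np.sort(factors["growth_year"].unique())

    # linear predictor per (site, year) from the true betas
    signal = pd.Series(0.0, index=pd.MultiIndex.from_product(
        [sites, years], names=["site_id", "growth_year"]))
    if truth.beta:
        fac = factors.set_index(["factor", "season", "lag"]).sort_index()
        for key, b in truth.beta.items():
            try:
                sub = fac.loc[key]
            except KeyError:
                raise KeyError(f"factor key {key!r} missing from factors")
            contrib = sub.set_index(["site_id", "growth_year"])["std_value"]
            contrib = contrib.reindex(signal.index)
            if contrib.isna().any():
                raise KeyError(
                    f"factor key {key!r} does not cover every (site, year)"
                )
            signal = signal + b * contrib

    site_eff = dict(zip(sites, rng.normal(0.0, truth.site_intercept_sd,
                                          len(sites))))
    rows = []
    n_years = len(years)
    for site in sites:
        for t in range(truth.trees_per_site):
            a0, a1 = truth.age_at_start_range
            start_age = int(rng.integers(a0, a1 + 1))
            ages = start_age + np.arange(n_years)
            eps = rng.normal(0.0, truth.residual_sd, n_years)
            w = (age_curve(ages.astype(float), truth.age_params)
                 + signal.loc[site].to_numpy()
                 + site_eff[site] + eps)
            rows.append(pd.DataFrame({
                "species": truth.species, "site_id": site,
                "tree_id": f"{site}-t{t + 1}", "year": years,
                "age": ages, "width_mm": w,
            }))
    out = pd.concat(rows, ignore_index=True)
    floored = out["width_mm"] < 0.01
    if floored.any():
        log.info("floored %d negative ring width(s) at 0.01 mm",
                 int(floored.sum()))
    out["floored"] = floored
    out.loc[floored, "width_mm"] = 0.01
    return out


def write_rings_csv(rings: pd.DataFrame, path) -> None:
    cols = ["species", "site_id", "tree_id", "year", "age", "width_mm"]
    rings[cols].to_csv(path, index=False)


def read_rings_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
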