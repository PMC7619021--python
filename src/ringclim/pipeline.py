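"""End-to-end synthetic study driver.

Wires the modules into the full chain: per-site daily weather ->
phenology gate -> water balance -> seasonal growth factors (frozen
standardisation) -> ring series with known ground truth -> age
detrending -> screening/preselection/stepwise mixed model -> scenario
projection.  Used by the validation suite and the reproduction script;
all randomness flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import age_detrend, sensitivity
from .age_detrend import SPECIES_AGE_PARAMS, AgeCurveParams
from .climate import ScenarioSpec, apply_scenario, build_baseline_loop, \
    ensure_radiation
from .growth_factors import DEFAULT_REFERENCE_WINDOW, Standardizer, \
    attach_lags, build_raw_factors, to_wide
from .phenology import PhenoParams, in_leaf_mask
from .projection import period_summary, project
from .synthetic_data import RingGenTruth, WeatherGenConfig, \
    generate_ring_series, generate_weather
from .water_balance import SoilParams, simulate

#: Default ground-truth effects (mm per SD), echoing realistic
#: magnitudes: wet early summers help, hot early summers hurt, mild
#: late winters of the previous year help.
DEFAULT_TRUE_BETA = {
    ("mean_soil_moisture", "Jun-Jul", "act"): 0.09,
    ("mean_temp", "Jun-Jul", "act"): -0.10,
    ("mean_temp", "Jan-Mar", "-1"): 0.05,
}


@dataclass(frozen=True)
class StudyConfig:
    """Conditions of the synthetic study."""

    n_sites: int = 63
    trees_per_site: int = 7
    start_year: int = 1931
    end_year: int = 2022
    projection_end_year: int = 2100
    latitude: float = 48.12
    elevation: float = 510.0
    species: str = "Fagus sylvatica"
    soil: SoilParams = field(default_factory=SoilParams)
    pheno: PhenoParams = field(default_factory=PhenoParams)
    age_params: AgeCurveParams = field(
        default_factory=lambda: SPECIES_AGE_PARAMS["Fagus sylvatica"])
    true_beta: dict = field(default_factory=lambda: dict(DEFAULT_TRUE_BETA))
    site_intercept_sd: float = 0.15
    residual_sd: float = 0.25
    reference_window: tuple[int, int] = DEFAULT_REFERENCE_WINDOW
    loop_source_window: tuple[str, str] = ("2001-01-01", "2020-12-31")
    seed: int = 1


def _site_seeds(cfg: StudyConfig) -> list[int]:
    rng = np.random.default_rng(cfg.seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, cfg.n_sites)]


def site_weather(cfg: StudyConfig, site_index: int,
                 seed: int) -> pd.DataFrame:
    wcfg = WeatherGenConfig(
        site_id=f"site-{site_index + 1:02d}",
        latitude=cfg.latitude,
        start_year=cfg.start_year, end_year=cfg.end_year,
        seed=seed,
    )
    return ensure_radiation(generate_weather(wcfg), cfg.latitude)


def extend_with_scenario(history: pd.DataFrame, cfg: StudyConfig,
                         scenario: ScenarioSpec) -> pd.DataFrame:
    """History + looped-and-modified future as one continuous series."""
    spec = replace(
        scenario,
        loop_source_window=cfg.loop_source_window,
        projection_window=(f"{cfg.end_year + 1}-01-01",
                           f"{cfg.projection_end_year}-12-31"),
    )
    future = build_baseline_loop(history, spec)
    future = apply_scenario(future, spec)
    cols = [c for c in history.columns]
    return pd.concat([history, future[cols]], ignore_index=True)


def run_site_daily(weather: pd.DataFrame, cfg: StudyConfig) -> pd.DataFrame:
    """Phenology gate + water balance for one site's daily weather."""
    leaf = in_leaf_mask(weather, cfg.latitude, cfg.pheno)
    wbm = simulate(weather, cfg.soil, in_leaf=leaf,
                   elevation=cfg.elevation, latitude=cfg.latitude)
    daily = wbm.copy()
    daily["tmean"] = weather["tmean"].to_numpy()
    daily["precip"] = weather["precip"].to_numpy()
    return daily


def build_study_factors(cfg: StudyConfig,
                        scenarios: dict[str, ScenarioSpec] | None = None):
    """Standardised factor tables for the historical window and,
    optionally, scenario extensions.

    Returns (hist_long, hist_wide, standardizer, scenario_tables) where
    ``scenario_tables`` maps scenario name to (long, wide) standardised
    with the frozen historical moments.
    """
    seeds = _site_seeds(cfg)
    hist_raw = []
    scen_raw: dict[str, list] = {k: [] for k in (scenarios or {})}
    for i, seed in enumerate(seeds):
        wx = site_weather(cfg, i, seed)
        site_id = f"site-{i + 1:02d}"
        daily = run_site_daily(wx, cfg)
        hist_raw.append(build_raw_factors(daily, site_id))
        for name, spec in (scenarios or {}).items():
            full = extend_with_scenario(wx, cfg, spec)
            daily_f = run_site_daily(full, cfg)
            scen_raw[name].append(build_raw_factors(daily_f, site_id))

    hist_lagged = attach_lags(pd.concat(hist_raw, ignore_index=True))
    std = Standardizer().fit(hist_lagged, cfg.reference_window)
    hist_long = std.transform(hist_lagged)
    hist_wide = to_wide(hist_long)

    scenario_tables = {}
    for name, parts in scen_raw.items():
        lagged = attach_lags(pd.concat(parts, ignore_index=True))
        long = std.transform(lagged)
        scenario_tables[name] = (long, to_wide(long))
    return hist_long, hist_wide, std, scenario_tables


def make_truth(cfg: StudyConfig, seed: int) -> RingGenTruth:
    return RingGenTruth(
        age_params=cfg.age_params, beta=dict(cfg.true_beta),
        site_intercept_sd=cfg.site_intercept_sd,
        residual_sd=cfg.residual_sd, n_sites=cfg.n_sites,
        trees_per_site=cfg.trees_per_site, species=cfg.species,
        seed=seed,
    )


def fit_study(rings: pd.DataFrame, hist_long: pd.DataFrame,
              hist_wide: pd.DataFrame, species: str,
              age_params: AgeCurveParams | None = None
              ) -> tuple[sensitivity.SensitivityModel, list]:
    """Detrend, screen, preselect and stepwise-fit one species.

    The age curve is refitted from the data unless ``age_params`` is
    given.  Returns the reduced model and the candidate list.
    """
    if age_params is None:
        mean_w = age_detrend.mean_width_by_age(rings)
        age_params, _ = age_detrend.fit_age_curve(mean_w)
    resid = age_detrend.detrend(rings, age_params)
    corr = sensitivity.correlation_screen(resid, hist_long)
    candidates = sensitivity.preselect(corr)
    model = sensitivity.stepwise_aic(resid, hist_wide, candidates,
                                     species=species)
    return model, candidates


def analytic_projection_delta(true_beta: dict, scen_long: pd.DataFrame,
                              base_long: pd.DataFrame,
                              period: tuple[int, int]) -> float:
    """Delta implied directly by the true coefficients: sum over terms
    of beta_j times the scenario-minus-baseline mean standardised
    factor over the period (sites and years pooled)."""
    y0, y1 = period

    def mean_std(long: pd.DataFrame, key) -> float:
        f, s, l = key
        sub = long[(long["factor"] == f) & (long["season"] == s)
                   & (long["lag"] == l)
                   & (long["growth_year"] >= y0)
                   & (long["growth_year"] <= y1)]
        return float(sub["std_value"].mean())

    return sum(b * (mean_std(scen_long, k) - mean_std(base_long, k))
               for k, b in true_beta.items())
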