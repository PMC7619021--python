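"""Beech growing-season phenology: leaf unfolding (LU) and coloring (LC).

LU is modelled by thermal forcing accumulation weighted by a
photoperiodic term: daily forcing is ``max(T - T_base, 0) *
(daylength/24)**photo_exponent`` accumulated from a start day; the leaf
unfolding day is the first day the running sum reaches ``F_crit``.

LC is a two-window linear temperature model: cool late springs and warm
late summers both delay the end of the growing season, so

    LC = lc_intercept - lc_coef_spring * Tbar_spring
                      + lc_coef_summer * Tbar_summer

with both coefficients constrained nonnegative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._solar import daylength_hours

#: Sentinel returned when the forcing requirement is never met in a year.
NO_EVENT = -1


@dataclass(frozen=True)
class PhenoParams:
    """Parameters of the LU forcing model and the LC linear model.

    Defaults are a single packaged beech parameterisation giving
    realistic Central-European event dates (LU near day 110-120, LC
    near day 285) under a temperate climate; they are substitutes for
    unpublished calibrations, not reconstructions of them.
    """

    t_base: float = 5.0            # degC forcing threshold
    photo_exponent: float = 1.0    # exponent on daylength/24
    f_crit: float = 70.0           # accumulated forcing units
    forcing_start_doy: int = 1
    lc_intercept: float = 270.0    # day of year
    lc_coef_spring: float = 1.0    # days per degC (advance)
    lc_coef_summer: float = 2.0    # days per degC (delay)
    spring_window: tuple[int, int] = (121, 181)   # May 1 - Jun 30
    summer_window: tuple[int, int] = (213, 273)   # Aug 1 - Sep 30

    def __post_init__(self):
        if self.f_crit <= 0:
            raise ValueError("f_crit must be positive")
        if self.photo_exponent < 0:
            raise ValueError("photo_exponent must be nonnegative")
        if not self.spring_window[0] <= self.spring_window[1]:
            raise ValueError("empty spring window")
        if not self.summer_window[0] <= self.summer_window[1]:
            raise ValueError("empty summer window")
        if self.spring_window[1] >= self.summer_window[0]:
            raise ValueError("spring window must precede summer window")


def _forcing_series(tmean: np.ndarray, doy: np.ndarray, latitude: float,
                    params: PhenoParams) -> np.ndarray:
    dl = daylength_hours(latitude, doy)
    photo = (dl / 24.0) ** params.photo_exponent
    forcing = np.maximum(tmean - params.t_base, 0.0) * photo
    forcing = np.where(doy >= params.forcing_start_doy, forcing, 0.0)
    return forcing


def predict_leaf_unfolding(weather: pd.DataFrame, latitude: float,
                           params: PhenoParams) -> int:
    """Leaf-unfolding day-of-year for one calendar year of daily weather.

    Returns :data:`NO_EVENT` if the accumulated forcing never reaches
    ``f_crit`` within the year.
    """
    dates = pd.DatetimeIndex(weather["date"])
    doy = dates.dayofyear.to_numpy()
    tmean = weather["tmean"].to_numpy(dtype=float)
    forcing = _forcing_series(tmean, doy, latitude, params)
    csum = np.cumsum(forcing)
    hit = np.nonzero(csum >= params.f_crit)[0]
    if hit.size == 0:
        return NO_EVENT
    return int(doy[hit[0]])


def _window_mean_temp(weather: pd.DataFrame, window: tuple[int, int]) -> float:
    doy = pd.DatetimeIndex(weather["date"]).dayofyear.to_numpy()
    mask = (doy >= window[0]) & (doy <= window[1])
    if not mask.any():
        raise ValueError(f"weather does not cover doy window {window}")
    return float(weather["tmean"].to_numpy(dtype=float)[mask].mean())


def predict_leaf_coloring(weather: pd.DataFrame, params: PhenoParams,
                          lu_doy: int | None = None) -> int:
    """Leaf-coloring day-of-year for one calendar year of daily weather.

    The raw linear prediction is rounded to the nearest day and clamped
    to [LU + 1, 365] (LU taken as 0 when unknown or absent).
    """
    t_spring = _window_mean_temp(weather, params.spring_window)
    t_summer = _window_mean_temp(weather, params.summer_window)
    raw = (params.lc_intercept
           - params.lc_coef_spring * t_spring
           + params.lc_coef_summer * t_summer)
    lo = (lu_doy + 1) if lu_doy is not None and lu_doy != NO_EVENT else 1
    return int(np.clip(round(raw), lo, 365))


def predict_growing_season(weather: pd.DataFrame, latitude: float,
                           params: PhenoParams) -> tuple[int, int]:
    """(LU, LC) day-of-year pair for one year of daily weather."""
    lu = predict_leaf_unfolding(weather, latitude, params)
    lc = predict_leaf_coloring(weather, params, lu_doy=lu)
    return lu, lc


def growing_season_table(weather: pd.DataFrame, latitude: float,
                         params: PhenoParams) -> pd.DataFrame:
    """(year, lu, lc) for every calendar year of a multi-year series.

    Array-based bulk counterpart of the per-year predict functions
    (identical results); years without a leaf-unfolding event carry
    lu = lc = :data:`NO_EVENT`.
    """
    dates = pd.DatetimeIndex(weather["date"])
    doy = dates.dayofyear.to_numpy()
    years = dates.year.to_numpy()
    tmean = weather["tmean"].to_numpy(dtype=float)
    forcing = _forcing_series(tmean, doy, latitude, params)
    sp0, sp1 = params.spring_window
    su0, su1 = params.summer_window
    rows = []
    for year in np.unique(years):
        sl = years == year
        d, f, t = doy[sl], forcing[sl], tmean[sl]
        csum = np.cumsum(f)
        hit = np.nonzero(csum >= params.f_crit)[0]
        if hit.size == 0:
            rows.append({"year": int(year), "lu": NO_EVENT, "lc": NO_EVENT})
            continue
        lu = int(d[hit[0]])
        t_sp = t[(d >= sp0) & (d <= sp1)].mean()
        t_su = t[(d >= su0) & (d <= su1)].mean()
        raw = (params.lc_intercept - params.lc_coef_spring * t_sp
               + params.lc_coef_summer * t_su)
        lc = int(np.clip(round(raw), lu + 1, 365))
        rows.append({"year": int(year), "lu": lu, "lc": lc})
    return pd.DataFrame(rows)


def in_leaf_mask(weather: pd.DataFrame, latitude: float,
                 params: PhenoParams) -> np.ndarray:
    """Boolean in-leaf flag per day of a multi-year daily series.

    Days in [LU, LC] of each calendar year are in leaf; years without a
    leaf-unfolding event stay out of leaf.
    """
    dates = pd.DatetimeIndex(weather["date"])
    doy = dates.dayofyear.to_numpy()
    years = dates.year.to_numpy()
    table = growing_season_table(weather, latitude, params)
    mask = np.zeros(len(weather), dtype=bool)
    for row in table.itertuples():
        if row.lu == NO_EVENT:
            continue
        sl = years == row.year
        mask[sl] = (doy[sl] >= row.lu) & (doy[sl] <= row.lc)
    return mask


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _split_years(weather: pd.DataFrame):
    years = pd.DatetimeIndex(weather["date"]).year
    return {int(y): sub for y, sub in weather.groupby(years)}


def _fit_f_crit(csums: dict[int, np.ndarray], doys: dict[int, np.ndarray],
                obs: dict[int, int]) -> tuple[float, float]:
    """Best F_crit (and its RMSE) for fixed T_base/exponent.

    Predicted LU is a step function of F_crit, so only forcing levels
    attained at some observed day can change the prediction; candidate
    thresholds are the accumulated forcing values at the observed event
    days across years (plus midpoints between consecutive levels).
    """
    levels = []
    for year, lu in obs.items():
        csum, doy = csums[year], doys[year]
        pos = np.searchsorted(doy, lu)
        if pos < len(csum):
            levels.append(csum[pos])
    levels = np.unique(np.asarray(levels))
    levels = levels[levels > 0]
    if levels.size == 0:
        return np.nan, np.inf
    cands = np.concatenate([levels, (levels[:-1] + levels[1:]) / 2.0])
    best = (np.nan, np.inf)
    for f in cands:
        errs = []
        for year, lu in obs.items():
            csum, doy = csums[year], doys[year]
            hit = np.nonzero(csum >= f)[0]
            pred = doy[hit[0]] if hit.size else 400  # penalise no-event
            errs.append(pred - lu)
        rmse = float(np.sqrt(np.mean(np.square(errs))))
        if rmse < best[1]:
            best = (float(f), rmse)
    return best


def fit_phenology(
    observations: pd.DataFrame,
    weather: pd.DataFrame,
    latitude: float,
    t_base_grid=np.arange(0.0, 8.5, 0.5),
    exponent_grid=(0.0, 0.5, 1.0, 1.5, 2.0),
) -> tuple[PhenoParams, dict]:
    """Fit LU and LC models to observed event days.

    ``observations`` has columns year, event (``BBCH11`` for LU,
    ``BBCH94`` for LC), doy.  LU is fitted by grid search over T_base
    and the photoperiod exponent with an inner 1-D solve for F_crit; LC
    by ordinary least squares on the two window mean temperatures with
    nonnegative coefficients.  Returns the fitted parameters and a dict
    of per-event RMSEs.
    """
    if len(observations) == 0:
        raise ValueError("empty observation set")
    lu_obs = {int(r.year): int(r.doy)
              for r in observations[observations["event"] == "BBCH11"].itertuples()}
    lc_obs = {int(r.year): int(r.doy)
              for r in observations[observations["event"] == "BBCH94"].itertuples()}
    years = _split_years(weather)

    if lu_obs and len(set(lu_obs.values())) == 1:
        warnings.warn("degenerate LU observations (all identical); "
                      "parameters are weakly constrained")

    params = PhenoParams()
    rmse: dict[str, float] = {}

    if lu_obs:
        doys = {y: pd.DatetimeIndex(years[y]["date"]).dayofyear.to_numpy()
                for y in lu_obs if y in years}
        tmeans = {y: years[y]["tmean"].to_numpy(dtype=float) for y in doys}
        usable = {y: v for y, v in lu_obs.items() if y in doys}
        if not usable:
            raise ValueError("no weather coverage for LU observation years")
        best = (np.inf, None)
        for t_base in t_base_grid:
            for expo in exponent_grid:
                csums = {}
                for y in usable:
                    f = _forcing_series(
                        tmeans[y], doys[y], latitude,
                        replace(params, t_base=float(t_base),
                                photo_exponent=float(expo)))
                    csums[y] = np.cumsum(f)
                f_crit, r = _fit_f_crit(csums, doys, usable)
                if r < best[0]:
                    best = (r, (float(t_base), float(expo), f_crit))
        rmse["BBCH11"] = best[0]
        t_base, expo, f_crit = best[1]
        params = replace(params, t_base=t_base, photo_exponent=expo,
                         f_crit=f_crit)

    if lc_obs:
        rows = []
        for y, lc in lc_obs.items():
            if y not in years:
                continue
            rows.append((
                _window_mean_temp(years[y], params.spring_window),
                _window_mean_temp(years[y], params.summer_window),
                lc,
            ))
        if not rows:
            raise ValueError("no weather coverage for LC observation years")
        arr = np.asarray(rows, dtype=float)
        # OLS with the model's sign convention: LC = b0 - b1*Tsp + b2*Tsu
        design = np.column_stack(
            [np.ones(len(arr)), -arr[:, 0], arr[:, 1]]
        )
        coef, *_ = np.linalg.lstsq(design, arr[:, 2], rcond=None)
        b0, b1, b2 = coef
        b1, b2 = max(b1, 0.0), max(b2, 0.0)  # enforce stated signs
        pred = b0 - b1 * arr[:, 0] + b2 * arr[:, 1]
        rmse["BBCH94"] = float(np.sqrt(np.mean((pred - arr[:, 2]) ** 2)))
        params = replace(params, lc_intercept=float(b0),
                         lc_coef_spring=float(b1), lc_coef_summer=float(b2))

    return params, rmse
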