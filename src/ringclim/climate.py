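"""Daily weather ingestion, radiation estimation and climate scenarios.

The canonical in-memory container for daily weather is a pandas
DataFrame with columns::

    date (datetime64), tmin, tmax, tmean [degC], precip [mm/day],
    rh [fraction], wind [m/s], and at least one of
    global_rad [MJ m-2 day-1] / sunshine_frac [fraction]

Future series are built by cyclically replaying a fixed historical
window (the "baseline loop"); scenario change is imposed on top of the
loop as a seasonal additive temperature offset and a multiplicative
precipitation factor, both ramped linearly from no change at the start
of the projection to an end-of-century endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from ._solar import daylength_hours, extraterrestrial_radiation
from .seasons import SEASONS, month_to_season

WEATHER_COLUMNS = ("date", "tmin", "tmax", "tmean", "precip", "rh", "wind")

#: FAO-56 default Angstrom-Prescott coefficients.
ANGSTROM_A = 0.25
ANGSTROM_B = 0.50


class WeatherValidationError(ValueError):
    """Raised when a daily weather table violates its invariants."""


def validate_weather(df: pd.DataFrame) -> pd.DataFrame:
    """Check invariants of a daily weather table and return it.

    Raises :class:`WeatherValidationError` on violations.
    """
    for col in WEATHER_COLUMNS:
        if col not in df.columns:
            raise WeatherValidationError(f"missing weather column {col!r}")
    if "global_rad" not in df.columns and "sunshine_frac" not in df.columns:
        raise WeatherValidationError(
            "need at least one of global_rad / sunshine_frac"
        )
    if not (df["tmin"] <= df["tmax"]).all():
        raise WeatherValidationError("tmin > tmax on some days")
    if (df["precip"] < 0).any():
        raise WeatherValidationError("negative precipitation")
    if ((df["rh"] < 0) | (df["rh"] > 1)).any():
        raise WeatherValidationError("rh outside [0, 1]")
    if "sunshine_frac" in df.columns:
        sf = df["sunshine_frac"].dropna()
        if ((sf < 0) | (sf > 1)).any():
            raise WeatherValidationError("sunshine_frac outside [0, 1]")
    return df


def read_weather_csv(path) -> pd.DataFrame:
    """Read the package's weather CSV dialect."""
    df = pd.read_csv(path, parse_dates=["date"])
    return validate_weather(df)


def write_weather_csv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def daylength(date, latitude: float):
    """Astronomical daylength in hours for a date (or dates)."""
    scalar = not isinstance(
        date, (list, tuple, np.ndarray, pd.Series, pd.DatetimeIndex)
    )
    dates = pd.DatetimeIndex(np.atleast_1d(pd.to_datetime(date)))
    dl = daylength_hours(latitude, dates.dayofyear.to_numpy())
    return float(dl[0]) if scalar and dl.size == 1 else dl


def estimate_radiation(
    sunshine_frac,
    date,
    latitude: float,
    a: float = ANGSTROM_A,
    b: float = ANGSTROM_B,
):
    """Angstrom-Prescott global radiation estimate, MJ m-2 day-1.

    Rg = Ra * (a + b * n/N) where n/N is the sunshine fraction and Ra
    the extraterrestrial radiation for the date and latitude.  During
    polar night Ra = 0 and the estimate is 0.
    """
    sf = np.clip(np.asarray(sunshine_frac, dtype=float), 0.0, 1.0)
    dates = pd.DatetimeIndex(np.atleast_1d(pd.to_datetime(date)))
    ra = extraterrestrial_radiation(latitude, dates.dayofyear.to_numpy())
    rg = ra * (a + b * sf)
    if np.isscalar(sunshine_frac) and rg.size == 1:
        return float(rg[0])
    return rg


def ensure_radiation(df: pd.DataFrame, latitude: float,
                     a: float = ANGSTROM_A, b: float = ANGSTROM_B) -> pd.DataFrame:
    """Return a copy with ``global_rad`` present, estimating it from the
    sunshine fraction where missing."""
    out = df.copy()
    if "global_rad" not in out.columns:
        out["global_rad"] = np.nan
    missing = out["global_rad"].isna()
    if missing.any():
        if "sunshine_frac" not in out.columns:
            raise WeatherValidationError(
                "global_rad missing and no sunshine_frac to estimate from"
            )
        est = estimate_radiation(
            out.loc[missing, "sunshine_frac"].to_numpy(),
            out.loc[missing, "date"], latitude, a=a, b=b,
        )
        out.loc[missing, "global_rad"] = est
    return out


def fill_gaps_by_regression(df: pd.DataFrame, reference: pd.DataFrame,
                            columns: tuple[str, ...]) -> pd.DataFrame:
    """Fill missing values of ``columns`` by linear regression on a
    reference series over overlapping days (station transfer).

    The minimal linear-transfer gap filler: for each variable a slope
    and intercept are estimated on days where both series are present.
    """
    out = df.copy()
    ref = reference.set_index("date")
    for col in columns:
        miss = out[col].isna()
        if not miss.any():
            continue
        merged = out.set_index("date")[[col]].join(
            ref[[col]], how="inner", rsuffix="_ref"
        ).dropna()
        if len(merged) < 2:
            raise WeatherValidationError(
                f"cannot fill {col!r}: fewer than 2 overlapping days"
            )
        slope, intercept = np.polyfit(merged[f"{col}_ref"], merged[col], 1)
        ref_vals = ref[col].reindex(out.loc[miss, "date"]).to_numpy()
        out.loc[miss, col] = intercept + slope * ref_vals
    return out


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioSpec:
    """Seasonal delta-change scenario over a baseline loop.

    ``temp_offset_endpoints`` / ``precip_mult_endpoints`` give, per
    season block, the additive temperature offset (degC) and the
    precipitation multiplier reached in ``horizon_year``.  Both ramp
    linearly from no change at ``ramp_start_year``; before the ramp the
    change is 0 (multiplier 1), after the horizon it stays at the
    endpoint.
    """

    name: str
    temp_offset_endpoints: dict = field(default_factory=dict)
    precip_mult_endpoints: dict = field(default_factory=dict)
    ramp_start_year: int = 2025
    horizon_year: int = 2100
    loop_source_window: tuple[str, str] = ("2001-01-01", "2020-12-31")
    projection_window: tuple[str, str] = ("2025-09-01", "2100-12-31")

    def __post_init__(self):
        for season, mult in self.precip_mult_endpoints.items():
            if mult < 0:
                raise ValueError(
                    f"negative precipitation multiplier for {season!r}"
                )

    def _ramp(self, year) -> np.ndarray:
        year = np.asarray(year, dtype=float)
        span = max(self.horizon_year - self.ramp_start_year, 1)
        return np.clip((year - self.ramp_start_year) / span, 0.0, 1.0)

    def temp_offset(self, season, year):
        """Additive offset (degC) for a season block and calendar year."""
        end = np.asarray(
            [self.temp_offset_endpoints.get(s, 0.0) for s in np.atleast_1d(season)]
        )
        out = end * self._ramp(year)
        return float(out[0]) if np.isscalar(season) and out.size == 1 else out

    def precip_multiplier(self, season, year):
        """Multiplicative precipitation factor for a season and year."""
        end = np.asarray(
            [self.precip_mult_endpoints.get(s, 1.0) for s in np.atleast_1d(season)]
        )
        out = 1.0 + (end - 1.0) * self._ramp(year)
        return float(out[0]) if np.isscalar(season) and out.size == 1 else out


def _rcp85_endpoints():
    # End-of-century deltas: ~+4 degC and +20% precipitation in winter,
    # ~+3 degC and +5% precipitation in summer; shoulder seasons between.
    temp = {"Jan-Mar": 4.0, "Apr-May": 3.5, "Jun-Jul": 3.0,
            "Aug-Sep": 3.0, "Oct-Dec": 4.0}
    prec = {"Jan-Mar": 1.20, "Apr-May": 1.12, "Jun-Jul": 1.05,
            "Aug-Sep": 1.05, "Oct-Dec": 1.20}
    return temp, prec


def default_scenarios() -> dict[str, ScenarioSpec]:
    """Packaged scenario table: baseline, rcp45, rcp85.

    The rcp45 endpoints are half the rcp85 change (temperature offsets
    halved, precipitation change halved).
    """
    t85, p85 = _rcp85_endpoints()
    t45 = {s: v / 2.0 for s, v in t85.items()}
    p45 = {s: 1.0 + (v - 1.0) / 2.0 for s, v in p85.items()}
    return {
        "baseline": ScenarioSpec("baseline"),
        "rcp45": ScenarioSpec("rcp45", t45, p45),
        "rcp85": ScenarioSpec("rcp85", t85, p85),
    }


def load_scenarios_yaml(path) -> dict[str, ScenarioSpec]:
    """Load a scenario table from YAML (see External Interfaces docs)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = {}
    for name, cfg in (raw.get("scenarios") or {}).items():
        out[name] = ScenarioSpec(
            name=name,
            temp_offset_endpoints=cfg.get("temp_offset_endpoints", {}),
            precip_mult_endpoints=cfg.get("precip_mult_endpoints", {}),
            ramp_start_year=cfg.get("ramp_start_year", 2025),
            horizon_year=cfg.get("horizon_year", 2100),
        )
    return out


def build_baseline_loop(history: pd.DataFrame, spec: ScenarioSpec) -> pd.DataFrame:
    """Fill the projection window by cyclically replaying the loop source.

    Projection day ``i`` (counting from the start of the projection
    window) receives the weather of source day ``i mod n_source``; dates
    are relabelled to the projection calendar.  A ``loop_date`` column
    records the source day each record came from.
    """
    start, end = (pd.Timestamp(d) for d in spec.loop_source_window)
    pstart, pend = (pd.Timestamp(d) for d in spec.projection_window)
    src = history[(history["date"] >= start) & (history["date"] <= end)]
    src = src.sort_values("date").reset_index(drop=True)
    expected = pd.date_range(start, end, freq="D")
    if len(src) != len(expected) or not (
        pd.DatetimeIndex(src["date"]) == expected
    ).all():
        have = set(pd.DatetimeIndex(src["date"]))
        gaps = [d.strftime("%Y-%m-%d") for d in expected if d not in have]
        raise WeatherValidationError(
            f"loop source window has {len(gaps)} missing day(s): "
            + ", ".join(gaps[:10])
        )
    proj_dates = pd.date_range(pstart, pend, freq="D")
    if len(proj_dates) == 0:
        out = src.iloc[:0].copy()
        out["loop_date"] = pd.Series([], dtype="datetime64[ns]")
        return out
    idx = np.arange(len(proj_dates)) % len(src)
    out = src.iloc[idx].reset_index(drop=True)
    out["loop_date"] = out["date"]
    out["date"] = proj_dates
    return out


def apply_scenario(series: pd.DataFrame, spec: ScenarioSpec) -> pd.DataFrame:
    """Apply the seasonal offset/multiplier of a scenario to a daily series.

    tmin/tmax are shifted by the seasonal offset, tmean recomputed as
    their mean; precipitation is multiplied by the seasonal factor.
    Humidity, wind and radiation are left unchanged.
    """
    out = series.copy()
    dates = pd.DatetimeIndex(out["date"])
    seasons = np.array([month_to_season(m) for m in dates.month])
    years = dates.year.to_numpy()
    offset = np.empty(len(out))
    mult = np.empty(len(out))
    for season in SEASONS:
        mask = seasons == season
        if not mask.any():
            continue
        offset[mask] = spec.temp_offset(
            np.repeat(season, mask.sum()), years[mask]
        )
        mult[mask] = spec.precip_multiplier(
            np.repeat(season, mask.sum()), years[mask]
        )
    if (mult < 0).any():
        raise ValueError("negative precipitation multiplier")
    out["tmin"] = out["tmin"] + offset
    out["tmax"] = out["tmax"] + offset
    out["tmean"] = (out["tmin"] + out["tmax"]) / 2.0
    out["precip"] = out["precip"] * mult
    return out
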