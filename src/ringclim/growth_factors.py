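"""Seasonal growth factors from daily weather and water-balance output.

Seven factors summarise each (site, calendar year, season block):
mean temperature, actual transpiration sum, climatic water balance
(precipitation minus actual transpiration), transpiration deficit sum,
mean soil moisture, and the counts of days with REW below 0.4 (severe)
and 0.7 (mild stress).  Each factor enters the growth model for the
current growth year ("act") and lagged by one and two years; factors
are standardised (z-scored) per (factor, season, lag) stratum over a
fixed historical reference window whose moments are frozen and reused
for scenario data.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import yaml

from .seasons import LAGS, SEASON_MONTHS, SEASONS, is_legal_key, month_to_season
from .water_balance import count_stress_days

log = logging.getLogger(__name__)

FACTORS = (
    "mean_temp",
    "transp_sum",
    "climatic_wb",
    "transp_deficit",
    "mean_soil_moisture",
    "days_rew_lt_04",
    "days_rew_lt_07",
)

#: Default standardisation reference window (growth years, inclusive).
DEFAULT_REFERENCE_WINDOW = (1933, 2022)


def _season_window_dates(year: int, season: str) -> pd.DatetimeIndex:
    m0, m1 = SEASON_MONTHS[season]
    start = pd.Timestamp(year, m0, 1)
    end = pd.Timestamp(year, m1, 1) + pd.offsets.MonthEnd(0)
    return pd.date_range(start, end, freq="D")


def aggregate_season(daily: pd.DataFrame, year: int, season: str,
                     strict_thresholds: bool = True) -> dict[str, float]:
    """The seven raw factor values for one season window of one year.

    ``daily`` is a merged daily table with at least date, tmean,
    precip, t_act, t_pot, theta, rew.  Raises if the window has gaps,
    listing the missing dates.
    """
    window = _season_window_dates(year, season)
    dates = pd.DatetimeIndex(daily["date"])
    mask = (dates >= window[0]) & (dates <= window[-1])
    sub = daily.loc[mask]
    if len(sub) != len(window):
        have = set(pd.DatetimeIndex(sub["date"]))
        gaps = [d.strftime("%Y-%m-%d") for d in window if d not in have]
        raise ValueError(
            f"{season} {year}: {len(gaps)} missing day(s): "
            + ", ".join(gaps[:10])
        )
    t_act = sub["t_act"].to_numpy(dtype=float)
    t_pot = sub["t_pot"].to_numpy(dtype=float)
    rew = sub["rew"].to_numpy(dtype=float)
    return {
        "mean_temp": float(sub["tmean"].mean()),
        "transp_sum": float(t_act.sum()),
        "climatic_wb": float(sub["precip"].sum() - t_act.sum()),
        "transp_deficit": float((t_pot - t_act).sum()),
        "mean_soil_moisture": float(sub["theta"].mean()),
        "days_rew_lt_04": float(count_stress_days(rew, 0.4,
                                                  strict=strict_thresholds)),
        "days_rew_lt_07": float(count_stress_days(rew, 0.7,
                                                  strict=strict_thresholds)),
    }


def build_raw_factors(daily: pd.DataFrame, site_id: str,
                      strict_thresholds: bool = True) -> pd.DataFrame:
    """Raw factors for every fully covered (year, season) of one site.

    Vectorised bulk counterpart of :func:`aggregate_season` (the two
    agree exactly on any shared window).  Season windows that extend
    beyond the daily series are skipped; a gap strictly inside the
    series raises.  Long format: site_id, year, season, factor,
    raw_value.
    """
    dates = pd.DatetimeIndex(daily["date"])
    rew = daily["rew"].to_numpy(dtype=float)
    df = pd.DataFrame({
        "year": dates.year,
        "season": [month_to_season(m) for m in dates.month],
        "tmean": daily["tmean"].to_numpy(dtype=float),
        "precip": daily["precip"].to_numpy(dtype=float),
        "t_act": daily["t_act"].to_numpy(dtype=float),
        "deficit": (daily["t_pot"].to_numpy(dtype=float)
                    - daily["t_act"].to_numpy(dtype=float)),
        "theta": daily["theta"].to_numpy(dtype=float),
        "sev": ((rew < 0.4) if strict_thresholds else (rew <= 0.4)
                ).astype(float),
        "mild": ((rew < 0.7) if strict_thresholds else (rew <= 0.7)
                 ).astype(float),
    })
    agg = df.groupby(["year", "season"]).agg(
        mean_temp=("tmean", "mean"),
        transp_sum=("t_act", "sum"),
        precip_sum=("precip", "sum"),
        transp_deficit=("deficit", "sum"),
        mean_soil_moisture=("theta", "mean"),
        days_rew_lt_04=("sev", "sum"),
        days_rew_lt_07=("mild", "sum"),
        n_days=("tmean", "size"),
    ).reset_index()
    agg["climatic_wb"] = agg["precip_sum"] - agg["transp_sum"]

    tmin_d, tmax_d = dates.min(), dates.max()
    keep = np.ones(len(agg), dtype=bool)
    for i, row in agg.iterrows():
        window = _season_window_dates(int(row["year"]), row["season"])
        if window[0] < tmin_d or window[-1] > tmax_d:
            keep[i] = False
        elif int(row["n_days"]) != len(window):
            raise ValueError(
                f"{row['season']} {int(row['year'])}: window has gaps "
                f"({int(row['n_days'])} of {len(window)} days present)"
            )
    agg = agg[keep]
    long = agg.melt(
        id_vars=["year", "season"], value_vars=list(FACTORS),
        var_name="factor", value_name="raw_value",
    )
    long.insert(0, "site_id", site_id)
    return long.reset_index(drop=True)


def build_raw_factors_multi(daily_by_site: dict[str, pd.DataFrame],
                            strict_thresholds: bool = True) -> pd.DataFrame:
    """Raw factors for several sites, concatenated."""
    return pd.concat(
        [build_raw_factors(df, site, strict_thresholds=strict_thresholds)
         for site, df in daily_by_site.items()],
        ignore_index=True,
    )


def attach_lags(raw: pd.DataFrame) -> pd.DataFrame:
    """Expand calendar-year factors into (growth_year, season, lag) rows.

    Lag "-1" copies the factor of calendar year growth_year - 1 and
    "-2" of growth_year - 2; "act" uses the growth year itself with
    Oct-Dec excluded.  Growth years whose lag years are not fully
    covered are dropped (logged).
    """
    years = raw["year"].unique()
    counts = raw.groupby("year")["factor"].count()
    full = len(SEASONS) * len(FACTORS)
    complete = {int(y) for y, c in counts.items() if c >= full}
    pieces = []
    dropped = set()
    for lag, shift in (("act", 0), ("-1", 1), ("-2", 2)):
        part = raw.copy()
        part["growth_year"] = part["year"] + shift
        part["lag"] = lag
        pieces.append(part)
    out = pd.concat(pieces, ignore_index=True)
    out = out[[is_legal_key(s, l) for s, l in zip(out["season"], out["lag"])]]

    def history_ok(gy: int) -> bool:
        return all((gy - k) in complete for k in (0, 1, 2))

    gy_all = sorted(out["growth_year"].unique())
    keep = {gy for gy in gy_all if history_ok(gy)}
    dropped = sorted(set(gy_all) - keep)
    if dropped:
        log.info("dropping %d growth year(s) with insufficient history: %s",
                 len(dropped), dropped[:5])
    out = out[out["growth_year"].isin(keep)]
    return (out[["site_id", "growth_year", "season", "lag", "factor",
                 "raw_value"]]
            .sort_values(["site_id", "growth_year", "season", "lag",
                          "factor"])
            .reset_index(drop=True))


class Standardizer:
    """Per-(factor, season, lag) z-scoring with frozen moments.

    Moments are computed once over a historical reference window,
    pooling sites and years, and reused unchanged for out-of-window
    (scenario) records.  Strata with zero variance are flagged
    constant: their std_value is 0 and they are marked excluded.
    """

    def __init__(self):
        self.moments: pd.DataFrame | None = None

    def fit(self, records: pd.DataFrame,
            reference_window: tuple[int, int] = DEFAULT_REFERENCE_WINDOW
            ) -> "Standardizer":
        y0, y1 = reference_window
        ref = records[(records["growth_year"] >= y0)
                      & (records["growth_year"] <= y1)]
        if ref["growth_year"].nunique() < 5:
            raise ValueError("reference window must contain >= 5 years")
        mom = (ref.groupby(["factor", "season", "lag"])["raw_value"]
               .agg(["mean", "std"]).reset_index())
        mom["std"] = mom["std"].fillna(0.0)
        mom["constant"] = mom["std"] == 0.0
        if mom["constant"].any():
            bad = mom.loc[mom["constant"], ["factor", "season", "lag"]]
            log.warning("constant factor strata excluded: %s",
                        bad.to_records(index=False).tolist())
        self.moments = mom
        self.reference_window = (int(y0), int(y1))
        return self

    def transform(self, records: pd.DataFrame) -> pd.DataFrame:
        if self.moments is None:
            raise RuntimeError("Standardizer not fitted")
        out = records.merge(self.moments, on=["factor", "season", "lag"],
                            how="left", validate="many_to_one")
        if out["mean"].isna().any():
            missing = out.loc[out["mean"].isna(),
                              ["factor", "season", "lag"]].drop_duplicates()
            raise KeyError("no moments for strata: "
                           + str(missing.to_records(index=False).tolist()))
        sd = out["std"].where(~out["constant"], 1.0)
        out["std_value"] = np.where(
            out["constant"], 0.0, (out["raw_value"] - out["mean"]) / sd
        )
        out["excluded_constant"] = out["constant"]
        return out.drop(columns=["mean", "std", "constant"])

    def save_yaml(self, path) -> None:
        data = {
            "reference_window": list(self.reference_window),
            "moments": self.moments.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)

    @classmethod
    def load_yaml(cls, path) -> "Standardizer":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        obj = cls()
        obj.moments = pd.DataFrame(data["moments"])
        obj.reference_window = tuple(data["reference_window"])
        return obj


def standardize(records: pd.DataFrame,
                reference_window: tuple[int, int] = DEFAULT_REFERENCE_WINDOW
                ) -> tuple[pd.DataFrame, Standardizer]:
    """Fit a :class:`Standardizer` on the reference window and apply it."""
    std = Standardizer().fit(records, reference_window)
    return std.transform(records), std


def to_wide(std_records: pd.DataFrame) -> pd.DataFrame:
    """Pivot standardised records to one column per (factor, season, lag).

    Columns are named ``factor|season|lag``; index columns are site_id
    and growth_year.
    """
    rec = std_records.copy()
    rec["key"] = (rec["factor"] + "|" + rec["season"] + "|" + rec["lag"])
    wide = rec.pivot_table(index=["site_id", "growth_year"],
                           columns="key", values="std_value")
    return wide.reset_index()
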