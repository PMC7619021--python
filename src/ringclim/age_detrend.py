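"""Species-specific age detrending of tree-ring widths.

Expected ring width as a function of cambial age is a hyperbolic
juvenile term plus a softplus-smoothed linear transition to a plateau:

    w_age(a) = p_n / a + p_s + w_min - 10 k ln(1 + exp(0.1 (p_m - a)))

with k = (w_min - w_50) / (p_m - 50) <= 0.  Near age 50 the softplus is
effectively linear, so w_age(50) ~ p_n/50 + p_s + w_50; for very old
trees the softplus vanishes and the curve levels off at p_s + w_min.
The climate signal is the residual w_res = w_obs - w_age.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

log = logging.getLogger(__name__)

RING_COLUMNS = ("species", "site_id", "tree_id", "year", "age", "width_mm")


@dataclass(frozen=True)
class AgeCurveParams:
    """The five parameters of the age-width curve (all widths in mm,
    ages in years)."""

    p_n: float    # hyperbolic juvenile term, mm * year
    p_s: float    # plateau offset, mm
    w_50: float   # width near age 50, mm
    w_min: float  # assumed minimum ring width, mm
    p_m: float    # transition age, years

    def __post_init__(self):
        if self.p_m <= 50:
            raise ValueError("p_m must exceed 50")
        if self.w_min > self.w_50:
            raise ValueError("w_min must not exceed w_50 (k <= 0)")
        if min(self.w_50, self.w_min) < 0 or self.p_n < 0 or self.p_s < 0:
            raise ValueError("widths and p_n/p_s must be nonnegative")

    @property
    def k(self) -> float:
        """Transition slope, mm/year (<= 0)."""
        return (self.w_min - self.w_50) / (self.p_m - 50.0)


#: Published per-species parameterisations of the age-width curve.
SPECIES_AGE_PARAMS: dict[str, AgeCurveParams] = {
    "Acer pseudoplatanus": AgeCurveParams(1.5, 0.00, 1.1, 0.7, 218.5),
    "Fagus sylvatica": AgeCurveParams(2.3, 0.00, 1.7, 0.9, 218.5),
    "Larix decidua": AgeCurveParams(25.3, 0.00, 1.0, 0.5, 141.3),
    "Picea abies": AgeCurveParams(9.0, 0.00, 1.9, 0.9, 92.0),
    "Pinus nigra": AgeCurveParams(14.6, 0.00, 1.0, 0.7, 151.6),
    "Pinus sylvestris": AgeCurveParams(22.2, 0.00, 1.1, 0.3, 121.5),
    "Quercus cerris": AgeCurveParams(9.9, 3.23, 1.6, 1.0, 112.0),
    "Quercus petraea": AgeCurveParams(13.8, 2.21, 1.3, 0.9, 143.2),
}


def _softplus(x):
    """Overflow-safe ln(1 + exp(x))."""
    x = np.asarray(x, dtype=float)
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))


def age_curve(age, params: AgeCurveParams):
    """Expected ring width (mm) at cambial age(s) ``age``."""
    age = np.asarray(age, dtype=float)
    if np.any(age <= 0):
        raise ValueError("age must be positive")
    w = (params.p_n / age + params.p_s + params.w_min
         - 10.0 * params.k * _softplus(0.1 * (params.p_m - age)))
    return float(w) if w.ndim == 0 else w


def mean_width_by_age(rings: pd.DataFrame) -> pd.DataFrame:
    """Assemble the per-age mean width timeline for one species."""
    out = (rings.groupby("age", as_index=False)["width_mm"]
           .mean().rename(columns={"width_mm": "mean_width_mm"}))
    return out.sort_values("age").reset_index(drop=True)


def _curve_vec(age, x, w_min):
    p_n, p_s, w_50, p_m = x
    k = (w_min - w_50) / (p_m - 50.0)
    return (p_n / age + p_s + w_min
            - 10.0 * k * _softplus(0.1 * (p_m - age)))


def fit_age_curve(mean_widths: pd.DataFrame,
                  w_min: float | None = None,
                  p_m_starts=(80.0, 120.0, 160.0, 220.0)
                  ) -> tuple[AgeCurveParams, dict]:
    """Least-squares fit of the age curve to a per-age mean series.

    ``mean_widths`` has columns age, mean_width_mm.  ``w_min`` is the
    assumed minimum ring width; it is an input, not a fitted parameter
    (the curve depends on the remaining four only through p_n,
    p_s + w_min, k and p_m, so all five are not jointly identifiable).
    When omitted, the smallest per-age mean width is assumed.

    Deterministic multistart over the transition age; reports r2 and
    adjusted r2 against the per-age mean series.  A near-flat fitted
    transition (|k| < 1e-6 mm/yr) is flagged in the returned stats.
    """
    age = mean_widths["age"].to_numpy(dtype=float)
    w = mean_widths["mean_width_mm"].to_numpy(dtype=float)
    if len(np.unique(age)) < 20:
        raise ValueError("need >= 20 distinct ages to fit the age curve")
    if w_min is None:
        w_min = float(w.min())

    w50_emp = float(w[np.argmin(np.abs(age - 50.0))])
    w50_emp = max(w50_emp, w_min + 1e-6)
    pn0 = max((w[np.argmin(age)] - w50_emp) * age.min(), 0.1)

    lo = [0.0, 0.0, max(w_min, 1e-3), 51.0]
    hi = [500.0, 10.0, 20.0, 400.0]

    def resid(x):
        return _curve_vec(age, x, w_min) - w

    best = None
    for pm0 in p_m_starts:
        x0 = np.clip([pn0, 0.0, w50_emp, pm0], lo, hi)
        try:
            res = optimize.least_squares(resid, x0, bounds=(lo, hi),
                                         method="trf")
        except Exception:  # pragma: no cover - pathological start
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise RuntimeError(
            "age-curve fit failed to converge from all starts"
        )
    p_n, p_s, w_50, p_m = best.x
    params = AgeCurveParams(p_n, p_s, w_50, w_min, p_m)
    pred = age_curve(age, params)
    ss_res = float(np.sum((w - pred) ** 2))
    ss_tot = float(np.sum((w - w.mean()) ** 2))
    n, p = len(w), 4
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    flat = abs(params.k) < 1e-6
    if flat:
        log.warning("fitted age curve is flat (k ~ 0)")
    stats = {"r2": r2, "adj_r2": adj_r2, "n_ages": n, "flat": flat,
             "rmse": float(np.sqrt(ss_res / n))}
    return params, stats


def detrend(rings: pd.DataFrame,
            params: AgeCurveParams | dict[str, AgeCurveParams]
            ) -> pd.DataFrame:
    """Attach w_age and w_res = w_obs - w_age to a ring table.

    ``params`` is either one parameter set or a per-species mapping.
    Rows with missing age are dropped (logged).
    """
    out = rings.copy()
    missing = out["age"].isna()
    if missing.any():
        log.warning("dropping %d ring(s) with missing age",
                    int(missing.sum()))
        out = out[~missing].copy()
    if isinstance(params, AgeCurveParams):
        out["w_age"] = age_curve(out["age"].to_numpy(dtype=float), params)
    else:
        out["w_age"] = np.nan
        for species, p in params.items():
            m = out["species"] == species
            if m.any():
                out.loc[m, "w_age"] = age_curve(
                    out.loc[m, "age"].to_numpy(dtype=float), p)
        unknown = out["w_age"].isna()
        if unknown.any():
            raise KeyError(
                "no age-curve parameters for species: "
                + ", ".join(sorted(out.loc[unknown, "species"].unique()))
            )
    out["w_res"] = out["width_mm"] - out["w_age"]
    return out
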