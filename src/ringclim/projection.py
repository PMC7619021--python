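"""Scenario projection of ring-width residuals to the end of the century.

A fitted sensitivity model is driven with scenario growth factors
standardised by the frozen historical moments; the predicted residual
per (site, year) is the fixed-effect linear predictor (random
intercepts set to zero, i.e. population-level prediction) averaged over
sites per year.  Trajectories are summarised as means over consecutive
20-year blocks anchored at 2001, and as deltas against the baseline
(looped-weather) scenario.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sensitivity import SensitivityModel

log = logging.getLogger(__name__)

PERIOD_ANCHOR = 2001


@dataclass
class ProjectionResult:
    """Annual predicted mean residuals for one species x scenario."""

    species: str
    scenario: str
    annual: pd.DataFrame                 # year, predicted_residual_mm
    per_site: pd.DataFrame = field(default_factory=pd.DataFrame)


def project(model: SensitivityModel, scenario_factors_wide: pd.DataFrame,
            scenario: str = "scenario") -> ProjectionResult:
    """Drive a fitted model with standardised scenario factors.

    ``scenario_factors_wide`` is the wide factor table (columns
    ``factor|season|lag``) standardised with the frozen historical
    moments.  Raises KeyError naming any retained term the scenario
    factors do not cover.
    """
    keys = [f"{f}|{s}|{l}" for f, s, l in model.retained_terms]
    missing = [k for k in keys if k not in scenario_factors_wide.columns]
    if missing:
        raise KeyError(f"scenario factors missing retained term(s): {missing}")
    df = scenario_factors_wide.dropna(subset=keys) if keys else \
        scenario_factors_wide
    if keys and len(df) < len(scenario_factors_wide):
        raise KeyError(
            "scenario factors have missing values for retained terms"
        )
    pred = np.full(len(df), model.intercept)
    for (term, key) in zip(model.retained_terms, keys):
        pred = pred + model.estimates[term] * df[key].to_numpy(dtype=float)
    per_site = pd.DataFrame({
        "site_id": df["site_id"], "year": df["growth_year"],
        "predicted_residual_mm": pred,
    })
    annual = (per_site.groupby("year", as_index=False)
              ["predicted_residual_mm"].mean())
    return ProjectionResult(species=model.species, scenario=scenario,
                            annual=annual, per_site=per_site)


def period_summary(annual: pd.DataFrame,
                   baseline_annual: pd.DataFrame | None = None,
                   block_years: int = 20,
                   anchor: int = PERIOD_ANCHOR) -> pd.DataFrame:
    """Means over consecutive ``block_years`` blocks anchored at ``anchor``.

    Only blocks fully covered by the series are reported; partial
    blocks are flagged in the log and excluded.  When a baseline series
    is given, a ``delta_vs_baseline_mm`` column is added per block
    (block missing from the baseline -> NaN delta).
    """
    ann = annual.sort_values("year")
    years = ann["year"].to_numpy()
    vals = ann["predicted_residual_mm"].to_numpy(dtype=float)
    block = (years - anchor) // block_years
    rows = []
    for b in np.unique(block):
        in_block = block == b
        start = anchor + int(b) * block_years
        end = start + block_years - 1
        if int(in_block.sum()) != block_years:
            log.info("excluding partial period %d-%d (%d of %d years)",
                     start, end, int(in_block.sum()), block_years)
            continue
        rows.append({"period_start": start, "period_end": end,
                     "mean_mm": float(vals[in_block].mean())})
    out = pd.DataFrame(rows)
    if baseline_annual is not None and len(out):
        base = period_summary(baseline_annual, None, block_years, anchor)
        base = base.rename(columns={"mean_mm": "baseline_mean_mm"})
        out = out.merge(base, on=["period_start", "period_end"], how="left")
        out["delta_vs_baseline_mm"] = out["mean_mm"] - out["baseline_mean_mm"]
    return out


def write_projection_csv(result: ProjectionResult, path) -> None:
    out = result.annual.copy()
    out.insert(0, "scenario", result.scenario)
    out.insert(0, "species", result.species)
    out.to_csv(path, index=False)
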