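"""Shared fixtures: small synthetic weather/study objects.

Everything is generated at run time from fixed seeds; the expensive
63-site study used by the validation-suite tests is session-scoped so
it is built once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ringclim import climate, phenology, pipeline, synthetic_data
from ringclim.climate import default_scenarios
from ringclim.water_balance import SoilParams


@pytest.fixture(scope="session")
def one_year_weather() -> pd.DataFrame:
    cfg = synthetic_data.WeatherGenConfig(start_year=2005, end_year=2005,
                                          seed=42)
    return climate.ensure_radiation(synthetic_data.generate_weather(cfg),
                                    cfg.latitude)


@pytest.fixture(scope="session")
def decade_weather() -> pd.DataFrame:
    cfg = synthetic_data.WeatherGenConfig(start_year=2001, end_year=2010,
                                          seed=7)
    return climate.ensure_radiation(synthetic_data.generate_weather(cfg),
                                    cfg.latitude)


@pytest.fixture(scope="session")
def loop_history() -> pd.DataFrame:
    """Daily weather covering the 2001-2020 loop source window."""
    cfg = synthetic_data.WeatherGenConfig(start_year=2001, end_year=2020,
                                          seed=3)
    return climate.ensure_radiation(synthetic_data.generate_weather(cfg),
                                    cfg.latitude)


@pytest.fixture(scope="session")
def soil() -> SoilParams:
    return SoilParams()


@pytest.fixture(scope="session")
def small_study():
    """A 4-site, 45-year study: factors + standardiser (fast)."""
    cfg = pipeline.StudyConfig(n_sites=4, start_year=1931, end_year=1975,
                               reference_window=(1933, 1975), seed=5)
    hist_long, hist_wide, std, _ = pipeline.build_study_factors(cfg)
    return cfg, hist_long, hist_wide, std


@pytest.fixture(scope="session")
def full_study():
    """The full 63-site, 90-year study with baseline and RCP8.5
    scenario factor tables (built once per session)."""
    cfg = pipeline.StudyConfig(seed=11)
    scen = default_scenarios()
    scenarios = {"baseline": scen["baseline"], "rcp85": scen["rcp85"]}
    hist_long, hist_wide, std, tables = pipeline.build_study_factors(
        cfg, scenarios=scenarios)
    return cfg, hist_long, hist_wide, std, tables
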