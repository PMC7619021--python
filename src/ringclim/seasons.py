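"""The five intra-annual season blocks and the act/-1/-2 lag system.

The growing season (April-September) is split into three two-month
blocks and the dormant season into two three-month blocks.  Growth
factors of the year of ring formation carry lag "act"; ring growth is
assumed complete by the end of September, so the October-December block
is illegal for "act" and only enters through the lagged years.
"""

from __future__ import annotations

#: Canonical season order (also the tie-break order wherever one is needed).
SEASONS = ("Jan-Mar", "Apr-May", "Jun-Jul", "Aug-Sep", "Oct-Dec")

#: Lags: current growth year, previous year, year before that.
LAGS = ("act", "-1", "-2")

_SEASON_OF_MONTH = {
    1: "Jan-Mar", 2: "Jan-Mar", 3: "Jan-Mar",
    4: "Apr-May", 5: "Apr-May",
    6: "Jun-Jul", 7: "Jun-Jul",
    8: "Aug-Sep", 9: "Aug-Sep",
    10: "Oct-Dec", 11: "Oct-Dec", 12: "Oct-Dec",
}

#: First and last month of each season block.
SEASON_MONTHS = {
    "Jan-Mar": (1, 3),
    "Apr-May": (4, 5),
    "Jun-Jul": (6, 7),
    "Aug-Sep": (8, 9),
    "Oct-Dec": (10, 12),
}


def month_to_season(month: int) -> str:
    """Map a calendar month (1-12) to its season block."""
    return _SEASON_OF_MONTH[month]


def is_legal_key(season: str, lag: str) -> bool:
    """Whether (season, lag) is a legal predictor key.

    (Oct-Dec, act) is excluded: it post-dates the assumed completion of
    ring formation in September.
    """
    if season not in SEASONS or lag not in LAGS:
        return False
    return not (season == "Oct-Dec" and lag == "act")


def legal_season_keys() -> list[tuple[str, str]]:
    """All 14 legal (season, lag) keys in canonical order.

    4 seasons for "act" plus 5 each for lags "-1" and "-2".
    """
    keys = []
    for lag in LAGS:
        for season in SEASONS:
            if is_legal_key(season, lag):
                keys.append((season, lag))
    return keys
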