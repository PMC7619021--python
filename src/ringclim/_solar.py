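"""Solar geometry helpers (FAO-56 conventions).

Shared by the radiation estimate, daylength computation, reference
evapotranspiration and the slope/aspect correction.  All functions are
vectorised over day-of-year.
"""

from __future__ import annotations

import numpy as np

#: Solar constant, MJ m-2 min-1 (FAO-56).
SOLAR_CONSTANT = 0.0820


def solar_declination(doy):
    """Solar declination in radians for day-of-year ``doy``."""
    doy = np.asarray(doy, dtype=float)
    return 0.409 * np.sin(2.0 * np.pi * doy / 365.0 - 1.39)


def inverse_rel_distance(doy):
    """Inverse relative earth-sun distance d_r (dimensionless)."""
    doy = np.asarray(doy, dtype=float)
    return 1.0 + 0.033 * np.cos(2.0 * np.pi * doy / 365.0)


def sunset_hour_angle(latitude_deg, doy):
    """Sunset hour angle in radians; clipped for polar day/night."""
    phi = np.deg2rad(latitude_deg)
    delta = solar_declination(doy)
    x = -np.tan(phi) * np.tan(delta)
    return np.arccos(np.clip(x, -1.0, 1.0))


def extraterrestrial_radiation(latitude_deg, doy):
    """Daily extraterrestrial radiation Ra in MJ m-2 day-1.

    Zero during polar night (sunset hour angle 0).
    """
    phi = np.deg2rad(latitude_deg)
    delta = solar_declination(doy)
    ws = sunset_hour_angle(latitude_deg, doy)
    dr = inverse_rel_distance(doy)
    ra = (24.0 * 60.0 / np.pi) * SOLAR_CONSTANT * dr * (
        ws * np.sin(phi) * np.sin(delta)
        + np.cos(phi) * np.cos(delta) * np.sin(ws)
    )
    return np.maximum(ra, 0.0)


def daylength_hours(latitude_deg, doy):
    """Astronomical daylength in hours, in [0, 24]."""
    return 24.0 / np.pi * sunset_hour_angle(latitude_deg, doy)
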