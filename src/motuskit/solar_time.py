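"""Sunset times and minutes-after-sunset.

All nocturnal-timing measures in the pipeline are referenced to local
sunset — the moment the centre of the solar disk reaches a zenith angle of
90.833 degrees (geometric horizon plus standard atmospheric refraction).
Times are computed with the NOAA solar-position algorithm, which is
accurate to well under two minutes at mid-latitudes.

A detection after local midnight still belongs to the *previous* evening's
night: :func:`minutes_after_sunset` measures from the sunset that opened
the ongoing solar night (any timestamp before local noon is referred to
the prior civil date's sunset).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd

__all__ = ["SolarContext", "sunset_utc", "minutes_after_sunset"]

#: maximum |latitude| supported; beyond this the sun may not set at all
#: during the season and the night-based bookkeeping breaks down.
POLAR_LAT = 66.5


@dataclass(frozen=True)
class SolarContext:
    """Location (WGS-84 decimal degrees) and sunset definition.

    zenith 90.833 deg = geometric horizon (90 deg) + 0.833 deg for
    refraction and the solar semi-diameter; the standard "sunset".
    """

    lat: float
    lon: float
    zenith: float = 90.833

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} outside [-180, 180]")
        if not 0.0 < self.zenith < 180.0:
            raise ValueError(f"zenith {self.zenith} outside (0, 180)")


def _julian_day_0h(d: date) -> float:
    """Julian day number at 00:00 UT of a civil date."""
    y, m, day = d.year, d.month, d.day
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return (math.floor(365.25 * (y + 4716))
            + math.floor(30.6001 * (m + 1)) + day + b - 1524.5)


def _solar_params(jd: float) -> tuple[float, float]:
    """Solar declination (deg) and equation of time (min) at a Julian day."""
    t = (jd - 2451545.0) / 36525.0
    l0 = (280.46646 + t * (36000.76983 + t * 0.0003032)) % 360.0
    m_deg = 357.52911 + t * (35999.05029 - 0.0001537 * t)
    ecc = 0.016708634 - t * (0.000042037 + 0.0000001267 * t)
    m = math.radians(m_deg)
    eq_ctr = (math.sin(m) * (1.914602 - t * (0.004817 + 0.000014 * t))
              + math.sin(2 * m) * (0.019993 - 0.000101 * t)
              + math.sin(3 * m) * 0.000289)
    omega = math.radians(125.04 - 1934.136 * t)
    app_long = l0 + eq_ctr - 0.00569 - 0.00478 * math.sin(omega)
    mean_obliq = (23.0 + (26.0 + (21.448 - t * (46.815 + t * (0.00059 - t * 0.001813))) / 60.0) / 60.0)
    obliq = mean_obliq + 0.00256 * math.cos(omega)
    decl = math.degrees(math.asin(math.sin(math.radians(obliq))
                                  * math.sin(math.radians(app_long))))
    var_y = math.tan(math.radians(obliq / 2.0)) ** 2
    l0r = math.radians(l0)
    eq_time = 4.0 * math.degrees(
        var_y * math.sin(2 * l0r)
        - 2 * ecc * math.sin(m)
        + 4 * ecc * var_y * math.sin(m) * math.cos(2 * l0r)
        - 0.5 * var_y ** 2 * math.sin(4 * l0r)
        - 1.25 * ecc ** 2 * math.sin(2 * m))
    return decl, eq_time


def sunset_utc(d: date | str | pd.Timestamp, ctx: SolarContext) -> pd.Timestamp:
    """UTC instant of sunset on civil date ``d`` at ``ctx``'s location.

    Two fixed-point passes over the NOAA equations (evaluating the slowly
    varying declination/equation-of-time at the provisional sunset hour)
    leave the result converged to well below one second.

    Raises
    ------
    ValueError
        for polar latitudes (|lat| >= 66.5 deg) or if the sun does not
        cross the requested zenith on that date.
    """
    if abs(ctx.lat) >= POLAR_LAT:
        raise ValueError(
            f"polar latitude {ctx.lat}: sunset undefined in part of the year; unsupported")
    if isinstance(d, str):
        d = pd.Timestamp(d).date()
    elif isinstance(d, pd.Timestamp):
        d = d.date()
    jd0 = _julian_day_0h(d)
    frac = 0.5
    minutes = math.nan
    for _ in range(3):
        decl, eq_time = _solar_params(jd0 + frac)
        cos_ha = (math.cos(math.radians(ctx.zenith))
                  / (math.cos(math.radians(ctx.lat)) * math.cos(math.radians(decl)))
                  - math.tan(math.radians(ctx.lat)) * math.tan(math.radians(decl)))
        if not -1.0 <= cos_ha <= 1.0:
            raise ValueError(
                f"sun does not cross zenith {ctx.zenith} at lat {ctx.lat} on {d}")
        ha = math.degrees(math.acos(cos_ha))
        solar_noon = 720.0 - 4.0 * ctx.lon - eq_time  # min past 0h UT
        minutes = solar_noon + 4.0 * ha
        frac = minutes / 1440.0
    base = pd.Timestamp(d, tz="UTC")
    return base + pd.Timedelta(minutes=minutes)


def _night_date(ts: pd.Timestamp, lon: float) -> date:
    """Civil date of the sunset opening the solar night containing ``ts``.

    Local apparent time is approximated by the longitude offset
    (lon / 15 hours); timestamps before local noon belong to the previous
    evening's night.
    """
    local = ts + pd.Timedelta(hours=lon / 15.0)
    d = local.date()
    if local.hour < 12:
        d = d - timedelta(days=1)
    return d


def minutes_after_sunset(ts: pd.Timestamp, ctx: SolarContext) -> float:
    """Signed minutes from the ongoing night's sunset to ``ts``.

    Negative values mean ``ts`` precedes that sunset (e.g. a late-afternoon
    detection).  ``ts`` must be timezone-aware.
    """
    ts = pd.Timestamp(ts)
    if ts.tzinfo is None:
        raise ValueError("timestamp must be timezone-aware")
    ts = ts.tz_convert("UTC")
    ss = sunset_utc(_night_date(ts, ctx.lon), ctx)
    return float((ts - ss) / pd.Timedelta(minutes=1))
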