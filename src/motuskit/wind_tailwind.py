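"""Wind interpolation and the tailwind component.

Wind support for a migratory flight is the projection of the wind vector
onto the flight bearing: ``tailwind = Vw * cos(beta)`` where Vw is wind
speed and beta the angle between the bearing and the direction the wind
blows *toward*.  With u the easterly (toward 090 deg) and v the northerly
(toward 000 deg) component, this equals ``u*sin(bearing) + v*cos(bearing)``;
both forms are computed and cross-asserted.  A bird flying south
(bearing 180 deg) in a 10 m/s northerly flow (v = -10) gets tailwind +10.

Wind is taken from a single pressure level (925 mb by default, roughly
675-825 m altitude — typical nocturnal thrush flight height) and
interpolated linearly in time and bilinearly in space to the departure
tower and first-detection instant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .telemetry_io import WindGrid

__all__ = ["WindVector", "TailwindResult", "interpolate_wind",
           "wind_speed_dir", "tailwind_component"]


@dataclass(frozen=True)
class WindVector:
    u: float  # m/s toward 090 deg (east)
    v: float  # m/s toward 000 deg (north)

    def __post_init__(self) -> None:
        if not (math.isfinite(self.u) and math.isfinite(self.v)):
            raise ValueError("wind components must be finite")


@dataclass(frozen=True)
class TailwindResult:
    Vw: float          # wind speed, m/s
    dir_toward: float  # direction wind blows toward, deg in [0, 360)
    beta: float        # bearing - dir_toward, deg
    tailwind: float    # m/s, positive = following wind


def _axis_fraction(values: np.ndarray, x: float, name: str) -> tuple[int, float]:
    """Bracketing lower index and linear fraction along a sorted axis."""
    if len(values) == 1:
        if not np.isclose(x, values[0]):
            raise ValueError(f"{name}={x} outside grid (single node {values[0]})")
        return 0, 0.0
    if x < values[0] or x > values[-1]:
        raise ValueError(
            f"{name}={x} outside grid range [{values[0]}, {values[-1]}]")
    i = int(np.searchsorted(values, x, side="right") - 1)
    i = min(i, len(values) - 2)
    frac = (x - values[i]) / (values[i + 1] - values[i])
    return i, float(frac)


def interpolate_wind(grid: WindGrid, ts, lat: float, lon: float) -> WindVector:
    """Trilinear (linear time x bilinear space) wind at a point instant.

    Out-of-bounds queries raise ``ValueError`` naming the offending axis.
    """
    ts = pd.Timestamp(ts)
    if ts.tzinfo is None:
        raise ValueError("timestamp must be timezone-aware")
    t = ts.tz_convert("UTC").value  # ns since epoch
    ti, tf = _axis_fraction(grid.times.asi8.astype(float), float(t), "time")
    yi, yf = _axis_fraction(grid.lats, lat, "lat")
    xi, xf = _axis_fraction(grid.lons, lon, "lon")

    def tri(a: np.ndarray) -> float:
        t2 = min(ti + 1, a.shape[0] - 1)
        y2 = min(yi + 1, a.shape[1] - 1)
        x2 = min(xi + 1, a.shape[2] - 1)
        c = a[np.ix_([ti, t2], [yi, y2], [xi, x2])]
        wt = np.array([1 - tf, tf])
        wy = np.array([1 - yf, yf])
        wx = np.array([1 - xf, xf])
        return float(np.einsum("i,j,k,ijk->", wt, wy, wx, c))

    return WindVector(u=tri(grid.u), v=tri(grid.v))


def wind_speed_dir(w: WindVector) -> tuple[float, float]:
    """Speed (m/s) and direction the wind blows toward, deg in [0, 360).

    Meteorological axis convention: 0 deg = toward north, 90 = toward east.
    """
    vw = math.hypot(w.u, w.v)
    direction = math.degrees(math.atan2(w.u, w.v)) % 360.0
    return vw, direction


def tailwind_component(w: WindVector, bearing_deg: float = 180.0) -> TailwindResult:
    """Tailwind (m/s) along a flight bearing; positive = following wind."""
    if not 0.0 <= bearing_deg < 360.0:
        raise ValueError("bearing must be in [0, 360)")
    vw, dir_toward = wind_speed_dir(w)
    beta = bearing_deg - dir_toward
    trig_form = vw * math.cos(math.radians(beta))
    b = math.radians(bearing_deg)
    vector_form = w.u * math.sin(b) + w.v * math.cos(b)
    assert abs(trig_form - vector_form) <= 1e-9 * max(1.0, vw), \
        "tailwind trig/vector forms disagree"
    return TailwindResult(Vw=vw, dir_toward=dir_toward, beta=beta,
                          tailwind=vector_form)
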