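"""First-flight speed across the water barrier.

A tag passing a receiver traces a parabolic arc in signal strength —
rising on approach, falling after passage — so the least-squares quadratic
vertex of signal on time estimates the closest-approach ("peak passage")
instant.  Crossing speed is the great-circle distance between the last
north-shore tower and the first south-shore tower divided by the time
between their signal peaks, for birds detected on both shores the same
night.  Passes without a *clear* peak (interior vertex, negative
curvature, adequate fit and point count) cannot yield a reliable passage
time and are excluded with a reason.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd

from .solar_time import SolarContext, sunset_utc
from .wind_tailwind import interpolate_wind, tailwind_component

if TYPE_CHECKING:  # pragma: no cover
    from .detection_filtering import Run
    from .departure_events import DepartureEvent
    from .telemetry_io import WindGrid

__all__ = ["PeakFit", "CrossingRecord", "fit_signal_peak", "haversine_km",
           "build_crossing", "night_of"]

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius


@dataclass(frozen=True)
class PeakFit:
    """Quadratic signal-peak fit for one receiver pass."""

    peak_ts: pd.Timestamp
    curvature: float  # quadratic coefficient, dB/s^2; clear peaks are < 0
    r2: float
    n_points: int
    clear: bool


@dataclass(frozen=True)
class CrossingRecord:
    """One bird's barrier crossing, peak-to-peak."""

    tag_id: str
    north_recv: str
    south_recv: str
    peak_north_ts: pd.Timestamp
    peak_south_ts: pd.Timestamp
    distance_km: float
    duration_h: float
    speed_kmh: float
    tailwind_mps: float

    def __post_init__(self) -> None:
        if self.peak_south_ts <= self.peak_north_ts:
            raise ValueError("south peak must follow north peak")
        if not (self.speed_kmh > 0 and math.isfinite(self.speed_kmh)):
            raise ValueError("speed must be positive and finite")


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance on a sphere of radius 6371.0088 km."""
    for val, bound, name in ((lat1, 90, "lat1"), (lat2, 90, "lat2"),
                             (lon1, 180, "lon1"), (lon2, 180, "lon2")):
        if not abs(val) <= bound:
            raise ValueError(f"{name}={val} out of range")
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def fit_signal_peak(run: "Run", r2_threshold: float = 0.5,
                    min_points: int = 5) -> PeakFit:
    """OLS quadratic of signal on time; the vertex is the passage time.

    ``clear`` is True only when the parabola opens downward, the vertex
    lies strictly inside the run's time span, the fit explains at least
    ``r2_threshold`` of the signal variance, and the run has at least
    ``min_points`` bursts.
    """
    d = run.detections
    if len(d) < 3:
        raise ValueError("need >= 3 bursts to fit a quadratic")
    t0 = d["ts"].iloc[0]
    t = (d["ts"] - t0).dt.total_seconds().to_numpy()
    if np.ptp(t) == 0:
        raise ValueError("degenerate run: all detections share one timestamp")
    y = d["sig"].to_numpy(dtype=float)
    # center time for conditioning
    tc = t - t.mean()
    a, b, c = np.polyfit(tc, y, 2)
    yhat = np.polyval([a, b, c], tc)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    if a != 0:
        vertex_s = -b / (2 * a) + t.mean()
    else:
        vertex_s = math.nan
    interior = math.isfinite(vertex_s) and t[0] < vertex_s < t[-1]
    # a near-linear signal puts the vertex absurdly far away; report the
    # run midpoint and let `clear` carry the verdict
    usable = math.isfinite(vertex_s) and abs(vertex_s) < 10 * (t[-1] - t[0]) + 3600
    peak_ts = t0 + pd.Timedelta(seconds=vertex_s) if usable else run.mid_ts
    clear = bool(a < 0 and interior and r2 >= r2_threshold
                 and len(d) >= min_points)
    return PeakFit(peak_ts=peak_ts, curvature=float(a), r2=float(r2),
                   n_points=len(d), clear=clear)


def night_of(ts: pd.Timestamp, utc_offset_hours: float = -4.0):
    """Civil date of the night containing ``ts`` (sunset -> next noon).

    Uses a fixed UTC offset for "local" time; timestamps before local noon
    belong to the previous evening's night.
    """
    local = pd.Timestamp(ts).tz_convert("UTC") + pd.Timedelta(hours=utc_offset_hours)
    if local.hour < 12:
        local = local - pd.Timedelta(days=1)
    return local.date()


def build_crossing(event: "DepartureEvent", runs: Sequence["Run"],
                   towers: pd.DataFrame, wind: "WindGrid",
                   bearing_deg: float = 180.0, r2_threshold: float = 0.5,
                   min_points: int = 5, utc_offset_hours: float = -4.0,
                   ) -> tuple[CrossingRecord | None, str | None]:
    """Crossing record for one departing bird, or (None, reason).

    The bird's last origin-region run and first south-shore run of the
    departure night are paired; both must show a clear signal peak,
    mirroring the exclusion of birds "without a clear peak in signal
    strength".  Tailwind is evaluated at the north (departure) tower at
    the event's first-detection time, along ``bearing_deg``.
    """
    tower_ix = towers.set_index("recv_id")
    night = event.departure_date
    mine = [r for r in runs if r.tag_id == event.tag_id
            and night_of(r.mid_ts, utc_offset_hours) == night]
    north_runs = [r for r in mine
                  if tower_ix.loc[r.recv_id, "region"] == "origin"]
    south_runs = [r for r in mine
                  if tower_ix.loc[r.recv_id, "region"] == "south_shore"]
    if not north_runs:
        return None, "no origin-region run on departure night"
    if not south_runs:
        return None, "no south-shore run on departure night"
    north = max(north_runs, key=lambda r: (r.mid_ts, r.recv_id))
    north_fit = fit_signal_peak(north, r2_threshold, min_points) \
        if north.length >= 3 else PeakFit(north.mid_ts, 0.0, 0.0, north.length, False)
    if not north_fit.clear:
        return None, "no clear north peak"
    # earliest clear-peak south-shore run is "first"; ties break by tower id
    south = None
    south_fit = None
    for r in sorted(south_runs, key=lambda r: (r.mid_ts, r.recv_id)):
        fit = fit_signal_peak(r, r2_threshold, min_points) \
            if r.length >= 3 else PeakFit(r.mid_ts, 0.0, 0.0, r.length, False)
        if fit.clear:
            south, south_fit = r, fit
            break
    if south is None:
        return None, "no clear south peak"
    if south.mid_ts < north.mid_ts:
        raise ValueError(
            f"{event.tag_id}: south-shore run precedes last origin run")
    if south_fit.peak_ts <= north_fit.peak_ts:
        return None, "south peak not after north peak"
    nt = tower_ix.loc[north.recv_id]
    st = tower_ix.loc[south.recv_id]
    dist = haversine_km(nt["lat"], nt["lon"], st["lat"], st["lon"])
    duration_h = (south_fit.peak_ts - north_fit.peak_ts).total_seconds() / 3600.0
    w = interpolate_wind(wind, event.first_ts, float(nt["lat"]), float(nt["lon"]))
    tw = tailwind_component(w, bearing_deg)
    rec = CrossingRecord(
        tag_id=event.tag_id, north_recv=north.recv_id, south_recv=south.recv_id,
        peak_north_ts=north_fit.peak_ts, peak_south_ts=south_fit.peak_ts,
        distance_km=dist, duration_h=duration_h, speed_kmh=dist / duration_h,
        tailwind_mps=tw.tailwind)
    return rec, None
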