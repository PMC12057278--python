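"""Fall-migration departure detection and nocturnal timing.

A bird's departure night is the last night inside the migratory window
(Aug 25 - Oct 15) with a post-sunset detection at an origin-region
receiver, after which the bird is never detected in the origin region
again that calendar year.  The event time is the first detection after
sunset on that night, and the nocturnal-timing response is its offset from
local sunset in minutes.

Receivers cannot see the actual take-off, only the first detection near
the origin site, so one documented failure mode is a bird loitering in
range long after sunset; extreme late values are flagged (not deleted) by
an absolute cutoff and a gap-to-next-latest rule and excluded from
time-of-night analyses only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import date
from typing import Sequence

import pandas as pd

from .barrier_crossing import night_of
from .detection_filtering import Run
from .solar_time import SolarContext, minutes_after_sunset, sunset_utc

__all__ = ["DepartureEvent", "detect_departure", "detect_departures",
           "flag_time_outliers", "events_to_frame"]

MIGRATION_WINDOW = ("08-25", "10-15")


@dataclass(frozen=True)
class DepartureEvent:
    tag_id: str
    year: int
    departure_date: date        # civil date of the night's sunset
    first_ts: pd.Timestamp      # first post-sunset detection that night
    recv_id: str
    minutes_after_sunset: float
    outlier_flag: bool = False
    outlier_reason: str | None = None


def _window(year: int, window: tuple[str, str]) -> tuple[date, date]:
    return (pd.Timestamp(f"{year}-{window[0]}").date(),
            pd.Timestamp(f"{year}-{window[1]}").date())


def detect_departure(runs_for_tag: Sequence[Run], towers: pd.DataFrame,
                     window: tuple[str, str] = MIGRATION_WINDOW,
                     utc_offset_hours: float = -4.0) -> DepartureEvent | None:
    """Departure event for one bird, or None if it never departed cleanly.

    Absence is a valid outcome (bird died, tag failed, or origin
    detections continue past the window).
    """
    if not runs_for_tag:
        return None
    tag = runs_for_tag[0].tag_id
    tower_ix = towers.set_index("recv_id")
    origin = [r for r in runs_for_tag
              if tower_ix.loc[r.recv_id, "region"] == "origin"]
    if not origin:
        return None
    by_year: dict[int, list[Run]] = {}
    for r in origin:
        by_year.setdefault(r.start_ts.year, []).append(r)
    for year in sorted(by_year):
        runs = by_year[year]
        w0, w1 = _window(year, window)
        # candidate = last origin night of the year; must fall in-window
        last_night = max(night_of(r.end_ts, utc_offset_hours) for r in runs)
        if not w0 <= last_night <= w1:
            continue
        night_runs = [r for r in runs
                      if night_of(r.start_ts, utc_offset_hours) == last_night
                      or night_of(r.end_ts, utc_offset_hours) == last_night]
        # first post-sunset detection among that night's origin runs
        best_ts, best_recv = None, None
        for r in night_runs:
            ctx = SolarContext(lat=float(tower_ix.loc[r.recv_id, "lat"]),
                               lon=float(tower_ix.loc[r.recv_id, "lon"]))
            ss = sunset_utc(last_night, ctx)
            after = r.detections.loc[r.detections["ts"] > ss, "ts"]
            if len(after) and (best_ts is None or after.iloc[0] < best_ts):
                best_ts, best_recv = after.iloc[0], r.recv_id
        if best_ts is None:
            continue  # only pre-sunset detections on the last night
        ctx = SolarContext(lat=float(tower_ix.loc[best_recv, "lat"]),
                           lon=float(tower_ix.loc[best_recv, "lon"]))
        mas = minutes_after_sunset(best_ts, ctx)
        return DepartureEvent(tag_id=tag, year=year,
                              departure_date=last_night, first_ts=best_ts,
                              recv_id=best_recv, minutes_after_sunset=mas)
    return None


def detect_departures(runs: Sequence[Run], towers: pd.DataFrame,
                      window: tuple[str, str] = MIGRATION_WINDOW,
                      utc_offset_hours: float = -4.0) -> list[DepartureEvent]:
    """Departure events for every tag present in ``runs``."""
    by_tag: dict[str, list[Run]] = {}
    for r in runs:
        by_tag.setdefault(r.tag_id, []).append(r)
    events = []
    for tag in sorted(by_tag):
        ev = detect_departure(by_tag[tag], towers, window, utc_offset_hours)
        if ev is not None:
            events.append(ev)
    return events


def flag_time_outliers(events: Sequence[DepartureEvent],
                       abs_cutoff_min: float = 300.0,
                       gap_cutoff_min: float = 60.0) -> list[DepartureEvent]:
    """Flag extreme minutes-after-sunset values (flag-and-exclude).

    An event is flagged when its value exceeds ``abs_cutoff_min``, or
    exceeds the next-largest value in the set by more than
    ``gap_cutoff_min``.  Flagged events stay in the output (and in all
    non-timing analyses); only the flag changes.
    """
    events = list(events)
    out: list[DepartureEvent] = []
    values = sorted(e.minutes_after_sunset for e in events)
    for e in events:
        reasons = []
        if e.minutes_after_sunset > abs_cutoff_min:
            reasons.append(f"abs>{abs_cutoff_min:g}min")
        if len(values) >= 2 and e.minutes_after_sunset == values[-1]:
            below = [v for v in values if v < e.minutes_after_sunset]
            if below and e.minutes_after_sunset - max(below) > gap_cutoff_min:
                reasons.append(f"gap>{gap_cutoff_min:g}min")
        if reasons:
            out.append(replace(e, outlier_flag=True,
                               outlier_reason=";".join(reasons)))
        else:
            out.append(e)
    return out


def events_to_frame(events: Sequence[DepartureEvent]) -> pd.DataFrame:
    cols = ["tag_id", "year", "departure_date", "first_ts", "recv_id",
            "minutes_after_sunset", "outlier_flag", "outlier_reason"]
    return pd.DataFrame(
        [{c: getattr(e, c) for c in cols} for e in events], columns=cols)
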