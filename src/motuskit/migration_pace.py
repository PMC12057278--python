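"""Tower-to-tower southbound sections and migration pace (km/day).

Sparse receiver coverage south of the barrier cannot separate flight from
stopover, but the elapsed time between detections at two towers, divided
into the great-circle distance between them, gives an average pace that
blends both.  Sections whose endpoints fall on the same or consecutive
calendar days are dropped — those measure a single overnight flight, not
stopover-inclusive pace.  Each section carries its midpoint latitude,
integer day span, and the bird's departure day-of-year as covariates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .barrier_crossing import fit_signal_peak, haversine_km
from .detection_filtering import Run
from .departure_events import DepartureEvent

__all__ = ["PaceSection", "build_sections", "summarize_pace", "sections_to_frame"]


@dataclass(frozen=True)
class PaceSection:
    tag_id: str
    recv_a: str
    recv_b: str
    ts_a: pd.Timestamp
    ts_b: pd.Timestamp
    distance_km: float
    elapsed_days: float   # fractional, for the km/day denominator
    km_per_day: float
    midpoint_lat: float
    days_between: int     # integer calendar-day difference (covariate)
    departure_doy: int

    def __post_init__(self) -> None:
        if self.ts_b <= self.ts_a:
            raise ValueError("section endpoints out of order")
        if self.days_between < 2:
            raise ValueError("consecutive-day sections are excluded")
        if not np.isclose(self.km_per_day, self.distance_km / self.elapsed_days):
            raise ValueError("km_per_day inconsistent with distance/elapsed")


def _endpoint_ts(run: Run) -> pd.Timestamp:
    """Run peak time when a clear peak exists, else the run midpoint."""
    if run.length >= 3:
        fit = fit_signal_peak(run)
        if fit.clear:
            return fit.peak_ts
    return run.mid_ts


def build_sections(post_departure_runs: Sequence[Run], towers: pd.DataFrame,
                   departures: Sequence[DepartureEvent]) -> list[PaceSection]:
    """Pace sections from each bird's southbound (corridor/south-shore) runs.

    Runs are ordered in time per bird; successive runs at *distinct*
    towers form a section.  Sections with endpoints on the same or
    consecutive calendar days (UTC) are dropped, mirroring the exclusion
    of direct-overnight-flight measurements.
    """
    tower_ix = towers.set_index("recv_id")
    dep_ix = {e.tag_id: e for e in departures}
    by_tag: dict[str, list[Run]] = {}
    for r in post_departure_runs:
        region = tower_ix.loc[r.recv_id, "region"]
        if region in ("corridor", "south_shore") and r.tag_id in dep_ix:
            by_tag.setdefault(r.tag_id, []).append(r)
    sections: list[PaceSection] = []
    for tag in sorted(by_tag):
        runs = sorted(by_tag[tag], key=lambda r: (r.mid_ts, r.recv_id))
        dep = dep_ix[tag]
        doy = int(pd.Timestamp(dep.departure_date).dayofyear)
        prev = None
        for r in runs:
            if prev is not None and r.recv_id != prev.recv_id:
                ts_a, ts_b = _endpoint_ts(prev), _endpoint_ts(r)
                days_between = abs((ts_b.date() - ts_a.date()).days)
                if ts_b > ts_a and days_between >= 2:
                    a, b = tower_ix.loc[prev.recv_id], tower_ix.loc[r.recv_id]
                    dist = haversine_km(a["lat"], a["lon"], b["lat"], b["lon"])
                    elapsed = (ts_b - ts_a).total_seconds() / 86400.0
                    sections.append(PaceSection(
                        tag_id=tag, recv_a=prev.recv_id, recv_b=r.recv_id,
                        ts_a=ts_a, ts_b=ts_b, distance_km=dist,
                        elapsed_days=elapsed, km_per_day=dist / elapsed,
                        midpoint_lat=(float(a["lat"]) + float(b["lat"])) / 2.0,
                        days_between=days_between, departure_doy=doy))
            prev = r
    return sections


def summarize_pace(sections: Sequence[PaceSection],
                   ages: dict[str, str] | None = None) -> pd.DataFrame:
    """n sections/birds and mean +- SE km/day, overall and by age class.

    ``ages`` maps tag_id -> age class; without it only the overall row is
    produced.  An empty input yields a single all-NaN marker row.
    """
    if not sections:
        return pd.DataFrame([{"group": "overall", "n_sections": 0, "n_birds": 0,
                              "mean_km_per_day": np.nan, "se_km_per_day": np.nan,
                              "min_km_per_day": np.nan, "max_km_per_day": np.nan}])
    df = sections_to_frame(sections)
    df["group"] = "overall"
    frames = [df]
    if ages:
        by_age = df.drop(columns="group").copy()
        by_age["group"] = by_age["tag_id"].map(ages)
        frames.append(by_age)
    rows = []
    for g, grp in pd.concat(frames).groupby("group", sort=True):
        vals = grp["km_per_day"]
        rows.append({
            "group": g, "n_sections": len(grp),
            "n_birds": grp["tag_id"].nunique(),
            "mean_km_per_day": float(vals.mean()),
            "se_km_per_day": float(vals.std(ddof=1) / np.sqrt(len(vals)))
            if len(vals) > 1 else np.nan,
            "min_km_per_day": float(vals.min()),
            "max_km_per_day": float(vals.max())})
    return pd.DataFrame(rows)


def sections_to_frame(sections: Sequence[PaceSection]) -> pd.DataFrame:
    cols = ["tag_id", "recv_a", "recv_b", "ts_a", "ts_b", "distance_km",
            "elapsed_days", "km_per_day", "midpoint_lat", "days_between",
            "departure_doy"]
    return pd.DataFrame([{c: getattr(s, c) for c in cols} for s in sections],
                        columns=cols)
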