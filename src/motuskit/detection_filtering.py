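"""False-detection filters for coded-tag telemetry.

Automated receivers log spurious hits from radio noise and colliding tag
signals.  Two filters separate signal from noise:

* **run-length** — bursts are grouped into runs (consecutive bursts of one
  tag at one receiver, allowing a bounded number of missed bursts); runs
  shorter than 3 bursts are discarded as likely noise.
* **impossible locations** — runs implying absurd ground speeds between
  receivers, or matching declarative region/date exclusion rules, are
  discarded.

Both filters partition their input (kept + removed = input) and log every
removal with a reason code in {``short_run``, ``speed``, ``rule:<name>``}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .barrier_crossing import haversine_km

__all__ = ["Run", "ExclusionRule", "assemble_runs", "filter_short_runs",
           "filter_impossible", "runs_to_frame"]


@dataclass
class Run:
    """Consecutive bursts of one tag at one receiver."""

    tag_id: str
    recv_id: str
    detections: pd.DataFrame  # columns tag_id, ts, recv_id, sig; time-ordered

    def __post_init__(self) -> None:
        d = self.detections
        if len(d) < 1:
            raise ValueError("a run needs at least one detection")
        if not (d["tag_id"] == self.tag_id).all() or not (d["recv_id"] == self.recv_id).all():
            raise ValueError("run mixes tags or receivers")
        if not d["ts"].is_monotonic_increasing:
            raise ValueError("run detections out of time order")

    @property
    def start_ts(self) -> pd.Timestamp:
        return self.detections["ts"].iloc[0]

    @property
    def end_ts(self) -> pd.Timestamp:
        return self.detections["ts"].iloc[-1]

    @property
    def length(self) -> int:
        return len(self.detections)

    @property
    def max_sig(self) -> float:
        return float(self.detections["sig"].max())

    @property
    def mid_ts(self) -> pd.Timestamp:
        return self.start_ts + (self.end_ts - self.start_ts) / 2


@dataclass(frozen=True)
class ExclusionRule:
    """Declarative impossible-location rule: region x date window.

    Runs at receivers in ``region`` whose start falls in
    [date_start, date_end] (inclusive, UTC civil dates) are removed.
    """

    name: str
    region: str
    date_start: str  # ISO date
    date_end: str


def assemble_runs(detections: pd.DataFrame, burst_interval_s: float,
                  gap_tolerance: float = 1.0, max_missed: int = 2) -> list[Run]:
    """Group detections into runs of consecutive bursts.

    Successive detections of the same tag at the same receiver extend a run
    iff their gap is within ``gap_tolerance`` of m x ``burst_interval_s``
    for an integer m <= 1 + ``max_missed`` (m-1 bursts missed); anything
    else starts a new run.
    """
    if burst_interval_s <= 0:
        raise ValueError("burst_interval_s must be > 0")
    det = detections.sort_values(["tag_id", "recv_id", "ts"], kind="mergesort")
    runs: list[Run] = []
    for (tag, recv), grp in det.groupby(["tag_id", "recv_id"], sort=True):
        gaps = grp["ts"].diff().dt.total_seconds().to_numpy()
        m = np.rint(gaps / burst_interval_s)
        ok = (np.abs(gaps - m * burst_interval_s) <= gap_tolerance) \
            & (m >= 1) & (m <= 1 + max_missed)
        ok[0] = False  # first detection always opens a run
        run_ids = np.cumsum(~ok)
        for _, sub in grp.groupby(run_ids, sort=True):
            runs.append(Run(tag_id=str(tag), recv_id=str(recv),
                            detections=sub.reset_index(drop=True)))
    runs.sort(key=lambda r: (r.tag_id, r.start_ts, r.recv_id))
    return runs


def filter_short_runs(runs: Sequence[Run], min_length: int = 3
                      ) -> tuple[list[Run], pd.DataFrame]:
    """Drop runs of fewer than ``min_length`` bursts (likely noise)."""
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    kept, removed = [], []
    for r in runs:
        if r.length >= min_length:
            kept.append(r)
        else:
            removed.append(_log_row(r, "short_run"))
    return kept, _log_frame(removed)


def filter_impossible(runs: Sequence[Run], deployments: pd.DataFrame,
                      towers: pd.DataFrame, max_ground_speed_kmh: float = 150.0,
                      rules: Iterable[ExclusionRule] = ()
                      ) -> tuple[list[Run], pd.DataFrame]:
    """Drop runs at impossible locations.

    A run is impossible when (a) reaching it from the previous kept run of
    the same tag would require ground speed above ``max_ground_speed_kmh``
    (run midpoints, great-circle distance), or (b) it matches a declarative
    region/date exclusion rule.  Rules are checked first, then speeds are
    evaluated sequentially along each tag's kept trajectory.
    """
    tower_ix = towers.set_index("recv_id")
    unknown = {r.recv_id for r in runs} - set(tower_ix.index)
    if unknown:
        raise KeyError(f"receiver(s) not in tower table: {sorted(unknown)}")
    rules = list(rules)
    kept: list[Run] = []
    removed = []
    last_kept: dict[str, Run] = {}
    for r in sorted(runs, key=lambda r: (r.tag_id, r.mid_ts, r.recv_id)):
        trow = tower_ix.loc[r.recv_id]
        rule_hit = None
        for rule in rules:
            if (trow["region"] == rule.region
                    and pd.Timestamp(rule.date_start).date()
                    <= r.start_ts.date()
                    <= pd.Timestamp(rule.date_end).date()):
                rule_hit = rule
                break
        if rule_hit is not None:
            removed.append(_log_row(r, f"rule:{rule_hit.name}"))
            continue
        prev = last_kept.get(r.tag_id)
        if prev is not None and prev.recv_id != r.recv_id:
            p = tower_ix.loc[prev.recv_id]
            dist = haversine_km(p["lat"], p["lon"], trow["lat"], trow["lon"])
            hours = (r.mid_ts - prev.mid_ts).total_seconds() / 3600.0
            if hours <= 0 or dist / hours > max_ground_speed_kmh:
                removed.append(_log_row(r, "speed"))
                continue
        kept.append(r)
        last_kept[r.tag_id] = r
    return kept, _log_frame(removed)


def _log_row(r: Run, reason: str) -> dict:
    return {"tag_id": r.tag_id, "recv_id": r.recv_id, "start_ts": r.start_ts,
            "end_ts": r.end_ts, "length": r.length, "reason": reason}


def _log_frame(rows: list[dict]) -> pd.DataFrame:
    cols = ["tag_id", "recv_id", "start_ts", "end_ts", "length", "reason"]
    return pd.DataFrame(rows, columns=cols)


def runs_to_frame(runs: Sequence[Run]) -> pd.DataFrame:
    """Flatten runs to one summary row each (for logs and CSV output)."""
    return pd.DataFrame(
        [{"tag_id": r.tag_id, "recv_id": r.recv_id, "start_ts": r.start_ts,
          "end_ts": r.end_ts, "length": r.length, "max_sig": r.max_sig}
         for r in runs],
        columns=["tag_id", "recv_id", "start_ts", "end_ts", "length", "max_sig"])
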