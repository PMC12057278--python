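"""End-to-end orchestration: filter -> departures -> crossings -> pace -> models.

The pipeline consumes the telemetry_io file formats (or in-memory frames),
applies the detection filters, extracts departure events with nocturnal
timing, builds barrier-crossing records with their tailwind covariate,
assembles southbound pace sections, and runs the four AICc model-selection
analyses.  Every exclusion is logged with a structured reason code, and
rerunning on identical inputs reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import telemetry_io as tio
from .barrier_crossing import build_crossing, night_of
from .departure_events import (DepartureEvent, detect_departures,
                               events_to_frame, flag_time_outliers)
from .detection_filtering import (ExclusionRule, assemble_runs,
                                  filter_impossible, filter_short_runs)
from .migration_pace import build_sections, sections_to_frame, summarize_pace
from .model_selection import GLOBAL_TERMS, aicc, run_response_analysis
from .synthetic_data import SimulationConfig, simulate_study

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
           "run_pipeline_frames", "simulate_and_run", "build_model_frames",
           "parameter_recovery_study"]


@dataclass
class PipelineConfig:
    """Resolved settings for one pipeline run."""

    detections: str | Path = "detections.csv"
    deployments: str | Path = "deployments.csv"
    towers: str | Path = "towers.csv"
    wind: str | Path = "wind.csv"
    output_dir: str | Path = "output"
    burst_interval_s: float = 12.7
    gap_tolerance_s: float = 1.0
    max_missed: int = 2
    min_run_length: int = 3
    max_ground_speed_kmh: float = 150.0
    rules: list[ExclusionRule] = field(default_factory=list)
    window: tuple[str, str] = ("08-25", "10-15")
    abs_outlier_min: float = 300.0
    gap_outlier_min: float = 60.0
    peak_r2_threshold: float = 0.5
    peak_min_points: int = 5
    bearing_deg: float = 180.0
    pressure_level_mb: float = 925.0
    utc_offset_hours: float = -4.0
    seed: int = 0

    def __post_init__(self) -> None:
        w0 = pd.Timestamp(f"2001-{self.window[0]}")
        w1 = pd.Timestamp(f"2001-{self.window[1]}")
        if w0 >= w1:
            raise ValueError("window start must precede window end")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["detections"] = str(d["detections"])
        d["deployments"] = str(d["deployments"])
        d["towers"] = str(d["towers"])
        d["wind"] = str(d["wind"])
        d["output_dir"] = str(d["output_dir"])
        d["rules"] = [dataclasses.asdict(r) if not isinstance(r, dict) else r
                      for r in d["rules"]]
        return d


@dataclass
class PipelineResult:
    events: list[DepartureEvent]
    departures: pd.DataFrame
    crossings: pd.DataFrame
    pace_sections: pd.DataFrame
    pace_summary: pd.DataFrame
    model_ranks: pd.DataFrame
    averaged_coefficients: pd.DataFrame
    analyses: dict
    run_log: pd.DataFrame


def _log(rows: list[dict], stage: str, reason: str, **kv) -> None:
    rows.append({"stage": stage, "reason": reason,
                 **{k: str(v) for k, v in kv.items()}})


def build_model_frames(departures: pd.DataFrame, crossings: pd.DataFrame,
                       sections: pd.DataFrame, deployments: pd.DataFrame
                       ) -> dict[str, pd.DataFrame]:
    """Per-response model frames with indicator coding.

    age: adult = 1, juvenile = 0; sex: male = 1, female = 0;
    year: numeric calendar year.
    """
    dep = deployments.set_index("tag_id")

    def covars(tags: pd.Series) -> pd.DataFrame:
        sub = dep.loc[tags]
        return pd.DataFrame({
            "age": (sub["age_class"] == "adult").astype(float).to_numpy(),
            "sex": (sub["sex"] == "male").astype(float).to_numpy(),
            "year": sub["year"].astype(float).to_numpy()})

    frames: dict[str, pd.DataFrame] = {}
    if len(departures):
        f = covars(departures["tag_id"])
        f["tag_id"] = departures["tag_id"].to_numpy()
        f["departure_doy"] = pd.to_datetime(
            departures["departure_date"].astype(str)).dt.dayofyear.astype(float)
        frames["departure_doy"] = f
        keep = ~departures["outlier_flag"].astype(bool)
        keep &= departures["minutes_after_sunset"] > 0
        t = covars(departures.loc[keep, "tag_id"])
        t["tag_id"] = departures.loc[keep, "tag_id"].to_numpy()
        t["minutes_after_sunset"] = departures.loc[keep, "minutes_after_sunset"].to_numpy()
        frames["minutes_after_sunset"] = t
    if len(crossings):
        s = covars(crossings["tag_id"])
        s["tag_id"] = crossings["tag_id"].to_numpy()
        s["speed_kmh"] = crossings["speed_kmh"].to_numpy()
        s["tailwind"] = crossings["tailwind_mps"].to_numpy()
        frames["speed_kmh"] = s
    if len(sections):
        p = covars(sections["tag_id"])
        p["tag_id"] = sections["tag_id"].to_numpy()
        for c in ("km_per_day", "midpoint_lat", "distance_km",
                  "days_between", "departure_doy"):
            p[c] = sections[c].astype(float).to_numpy()
        frames["km_per_day"] = p
    return frames


def _fit_all(frames: dict[str, pd.DataFrame], log_rows: list[dict]) -> dict:
    analyses = {}
    for response, frame in frames.items():
        terms = []
        for t in GLOBAL_TERMS[response]:
            parts = t.split(":")
            if all(frame[p].nunique() > 1 for p in parts):
                terms.append(t)
            else:
                _log(log_rows, "models", "constant_term_dropped",
                     response=response, term=t)
        max_k = len(terms) + 2 + (1 if response == "km_per_day" else 0)
        if len(frame) <= max_k + 2:
            _log(log_rows, "models", "insufficient_rows",
                 response=response, n=len(frame))
            continue
        analyses[response] = run_response_analysis(frame, response,
                                                   global_terms=tuple(terms))
    return analyses


def run_pipeline_frames(detections: pd.DataFrame, deployments: pd.DataFrame,
                        towers: pd.DataFrame, wind: tio.WindGrid,
                        config: PipelineConfig | None = None) -> PipelineResult:
    """Pipeline core on in-memory inputs; see :func:`run_pipeline`."""
    cfg = config or PipelineConfig()
    log_rows: list[dict] = []

    runs = assemble_runs(detections, cfg.burst_interval_s,
                         cfg.gap_tolerance_s, cfg.max_missed)
    kept, removed_short = filter_short_runs(runs, cfg.min_run_length)
    for _, r in removed_short.iterrows():
        _log(log_rows, "filter", r["reason"], tag_id=r["tag_id"],
             recv_id=r["recv_id"], start_ts=r["start_ts"])
    deployed = set(deployments["tag_id"])
    undeployed = [r for r in kept if r.tag_id not in deployed]
    for r in undeployed:
        _log(log_rows, "filter", "unknown_tag", tag_id=r.tag_id,
             recv_id=r.recv_id, start_ts=r.start_ts)
    kept = [r for r in kept if r.tag_id in deployed]
    kept, removed_imp = filter_impossible(kept, deployments, towers,
                                          cfg.max_ground_speed_kmh, cfg.rules)
    for _, r in removed_imp.iterrows():
        _log(log_rows, "filter", r["reason"], tag_id=r["tag_id"],
             recv_id=r["recv_id"], start_ts=r["start_ts"])

    events = detect_departures(kept, towers, cfg.window, cfg.utc_offset_hours)
    events = flag_time_outliers(events, cfg.abs_outlier_min, cfg.gap_outlier_min)
    for e in events:
        if e.outlier_flag:
            _log(log_rows, "departures", f"time_outlier:{e.outlier_reason}",
                 tag_id=e.tag_id, minutes=round(e.minutes_after_sunset, 1))
    departures = events_to_frame(events)

    crossing_rows = []
    for e in events:
        rec, reason = build_crossing(e, kept, towers, wind, cfg.bearing_deg,
                                     cfg.peak_r2_threshold, cfg.peak_min_points,
                                     cfg.utc_offset_hours)
        if rec is None:
            _log(log_rows, "crossings", reason.replace(" ", "_"), tag_id=e.tag_id)
        else:
            crossing_rows.append(dataclasses.asdict(rec))
    crossings = pd.DataFrame(crossing_rows, columns=[
        "tag_id", "north_recv", "south_recv", "peak_north_ts", "peak_south_ts",
        "distance_km", "duration_h", "speed_kmh", "tailwind_mps"])

    # pace uses only runs after each bird's departure night
    night_by_tag = {e.tag_id: e.departure_date for e in events}
    post = [r for r in kept
            if r.tag_id in night_by_tag
            and night_of(r.mid_ts, cfg.utc_offset_hours) >= night_by_tag[r.tag_id]]
    sections = build_sections(post, towers, events)
    sec_frame = sections_to_frame(sections)
    ages = dict(zip(deployments["tag_id"], deployments["age_class"]))
    pace_summary = summarize_pace(sections, ages)

    frames = build_model_frames(departures, crossings, sec_frame, deployments)
    n_nonpos = 0
    if "minutes_after_sunset" in frames:
        f = frames["minutes_after_sunset"]
        n_nonpos = int((f["minutes_after_sunset"] <= 0).sum())
        if n_nonpos:
            _log(log_rows, "models", "nonpositive_minutes_dropped", n=n_nonpos)
            frames["minutes_after_sunset"] = f[f["minutes_after_sunset"] > 0]
    analyses = _fit_all(frames, log_rows)

    rank_frames, avg_frames = [], []
    for response, res in analyses.items():
        t = res.table.copy()
        t.insert(0, "response", response)
        rank_frames.append(t)
        if res.averaged is not None:
            a = res.averaged.copy()
            a.insert(0, "response", response)
            avg_frames.append(a)
    model_ranks = pd.concat(rank_frames, ignore_index=True) if rank_frames \
        else pd.DataFrame(columns=["response", "terms", "loglik", "n", "k",
                                   "aicc", "delta_aicc", "weight"])
    averaged = pd.concat(avg_frames, ignore_index=True) if avg_frames \
        else pd.DataFrame(columns=["response", "coefficient", "estimate",
                                   "se", "lo95", "hi95"])
    run_log = pd.DataFrame(log_rows) if log_rows else \
        pd.DataFrame(columns=["stage", "reason"])
    return PipelineResult(events=events, departures=departures,
                          crossings=crossings, pace_sections=sec_frame,
                          pace_summary=pace_summary, model_ranks=model_ranks,
                          averaged_coefficients=averaged, analyses=analyses,
                          run_log=run_log)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full pipeline from files and write the output bundle.

    Writes departures.csv, crossings.csv, pace_sections.csv,
    model_ranks.csv, averaged_coefficients.csv, run_log.csv and the
    resolved configuration (resolved_config.json) to ``output_dir``.
    """
    stage = "read_inputs"
    try:
        detections = tio.read_detections(config.detections)
        deployments = tio.read_deployments(config.deployments)
        towers = tio.read_towers(config.towers)
        wind = tio.read_wind(config.wind)
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc
    result = run_pipeline_frames(detections, deployments, towers, wind, config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.departures.to_csv(outdir / "departures.csv", index=False)
    result.crossings.to_csv(outdir / "crossings.csv", index=False)
    result.pace_sections.to_csv(outdir / "pace_sections.csv", index=False)
    result.pace_summary.to_csv(outdir / "pace_summary.csv", index=False)
    result.model_ranks.to_csv(outdir / "model_ranks.csv", index=False)
    result.averaged_coefficients.to_csv(outdir / "averaged_coefficients.csv",
                                        index=False)
    result.run_log.to_csv(outdir / "run_log.csv", index=False)
    with open(outdir / "resolved_config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, default=str)
    return result


# ---------------------------------------------------------------------------
# simulation-recovery harness

def simulate_and_run(sim_config: SimulationConfig,
                     pipe_config: PipelineConfig | None = None) -> dict:
    """Generate a synthetic study, run the pipeline, compare to truth.

    Returns {"result", "bundle", "report", "summary"}: ``report`` has one
    row per simulated bird (truth vs estimate for departure night, minutes
    after sunset, crossing speed); ``summary`` aggregates error metrics
    and the model-selection outcome.
    """
    cfg = pipe_config or PipelineConfig(
        burst_interval_s=sim_config.burst_interval_s,
        utc_offset_hours=sim_config.utc_offset_hours,
        seed=sim_config.seed)
    bundle = simulate_study(sim_config)
    result = run_pipeline_frames(bundle["detections"], bundle["deployments"],
                                 bundle["towers"], bundle["wind"], cfg)
    ev_ix = {e.tag_id: e for e in result.events}
    cross_ix = result.crossings.set_index("tag_id") if len(result.crossings) \
        else None
    rows = []
    for s in bundle["schedules"]:
        true_night = night_of(s.true_departure_ts, sim_config.utc_offset_hours)
        e = ev_ix.get(s.tag_id)
        est_minutes = e.minutes_after_sunset if e else np.nan
        speed_est = np.nan
        if cross_ix is not None and s.tag_id in cross_ix.index:
            speed_est = float(cross_ix.loc[s.tag_id, "speed_kmh"])
        rows.append({
            "tag_id": s.tag_id, "age_class": s.age_class,
            "true_night": true_night,
            "est_night": e.departure_date if e else pd.NaT,
            "night_exact": bool(e and e.departure_date == true_night),
            "true_minutes": s.true_minutes_after_sunset,
            "est_minutes": est_minutes,
            "minutes_err": (est_minutes - s.true_minutes_after_sunset)
            if e else np.nan,
            "true_speed": s.true_groundspeed_kmh,
            "est_speed": speed_est,
            "speed_rel_err": (speed_est - s.true_groundspeed_kmh)
            / s.true_groundspeed_kmh if np.isfinite(speed_est) else np.nan,
        })
    report = pd.DataFrame(rows)
    detected = report["est_night"].notna()
    with_speed = report["speed_rel_err"].notna()
    summary = {
        "n_birds": len(report),
        "n_detected": int(detected.sum()),
        "night_exact_frac": float(report.loc[detected, "night_exact"].mean())
        if detected.any() else np.nan,
        "median_abs_minutes_err": float(report.loc[detected, "minutes_err"]
                                        .abs().median()) if detected.any() else np.nan,
        "n_crossings": int(len(result.crossings)),
        "max_abs_speed_rel_err": float(report.loc[with_speed, "speed_rel_err"]
                                       .abs().max()) if with_speed.any() else np.nan,
        "n_pace_sections": int(len(result.pace_sections)),
        "supported_terms": {
            resp: [" + ".join(f.terms) if f.terms else "(intercept)"
                   for f in res.supported]
            for resp, res in result.analyses.items()},
    }
    return {"result": result, "bundle": bundle, "report": report,
            "summary": summary}


def parameter_recovery_study(n_seeds: int, base_seed: int = 1,
                             **config_overrides) -> dict:
    """Replicate the synthetic study over seeds and score model selection.

    For each replicate: does the supported set contain age for the
    departure-date, time-of-night and pace responses, and do the averaged
    speed coefficients show tailwind (CI excluding zero) rather than age
    (CI including zero)?  Also pools the averaged effect estimates.
    Returns fractions in [0, 1] plus mean effects over the replicates.
    """
    counts = {"date_age_supported": 0, "time_age_supported": 0,
              "pace_age_supported": 0, "speed_tailwind_ci_excludes0": 0,
              "speed_age_ci_includes0": 0}
    effects: dict[str, list[float]] = {"date_age_effect": [],
                                       "time_age_log_effect": [],
                                       "speed_tailwind_coef": [],
                                       "pace_age_effect": []}
    sizes = {"n_crossings": [], "n_pace_sections": []}
    for i in range(n_seeds):
        seed = int((base_seed + 7919 * i) % (2 ** 31))
        out = simulate_and_run(SimulationConfig(seed=seed, **config_overrides))
        res = out["result"]
        sizes["n_crossings"].append(out["summary"]["n_crossings"])
        sizes["n_pace_sections"].append(out["summary"]["n_pace_sections"])
        for resp, key, eff_key, coef in [
                ("departure_doy", "date_age_supported", "date_age_effect", "age"),
                ("minutes_after_sunset", "time_age_supported",
                 "time_age_log_effect", "age"),
                ("km_per_day", "pace_age_supported", "pace_age_effect", "age")]:
            a = res.analyses.get(resp)
            if a and any("age" in f.terms for f in a.supported):
                counts[key] += 1
            if a and a.averaged is not None:
                av = a.averaged.set_index("coefficient")
                if coef in av.index:
                    effects[eff_key].append(float(av.loc[coef, "estimate"]))
        a = res.analyses.get("speed_kmh")
        if a and a.averaged is not None:
            av = a.averaged.set_index("coefficient")
            if "tailwind" in av.index:
                effects["speed_tailwind_coef"].append(
                    float(av.loc["tailwind", "estimate"]))
                if not av.loc["tailwind", "lo95"] <= 0 <= av.loc["tailwind", "hi95"]:
                    counts["speed_tailwind_ci_excludes0"] += 1
            if "age" not in av.index \
                    or av.loc["age", "lo95"] <= 0 <= av.loc["age", "hi95"]:
                counts["speed_age_ci_includes0"] += 1
    return {
        "n_seeds": n_seeds,
        "fractions": {k: v / n_seeds for k, v in counts.items()},
        "mean_effects": {k: float(np.mean(v)) if v else np.nan
                         for k, v in effects.items()},
        "mean_sizes": {k: float(np.mean(v)) for k, v in sizes.items()},
    }
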