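"""Readers and writers for every table and grid the pipeline touches.

All tabular interchange is CSV: UTF-8, comma-separated, header required,
RFC-4180 quoting.  Coordinates are WGS-84 decimal degrees.  Timestamps are
ISO-8601 with an explicit UTC offset (``Z`` and ``+00:00`` are equivalent);
naive timestamps are rejected.  Wind grids travel either as NetCDF
(dims time/lat/lon, variables u/v, attribute ``level``) or as a long CSV
(ts, lat, lon, level, u, v); both dialects yield identical grids.

Column dictionaries
-------------------
detections.csv   tag_id, ts, recv_id, sig
deployments.csv  tag_id, age_class, sex, year, deploy_lat, deploy_lon,
                 burst_interval_s
towers.csv       recv_id, lat, lon, region
truth.csv        tag_id, age_class, sex, year, true_departure_ts,
                 true_minutes_after_sunset, true_airspeed_kmh,
                 true_groundspeed_kmh, true_pace_per_section (;-joined)

Foreign exports (e.g. raw Motus downloads) are adapted with a
``column_map`` of ``ours=theirs`` renames — a mapping layer, not a hard
dependency on any particular export schema.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "WindGrid",
    "read_detections", "write_detections",
    "read_deployments", "write_deployments",
    "read_towers", "write_towers",
    "read_wind", "write_wind",
]

AGE_CLASSES = ("adult", "juvenile")
SEXES = ("male", "female")
REGIONS = ("origin", "south_shore", "corridor")

DETECTION_COLUMNS = ("tag_id", "ts", "recv_id", "sig")
DEPLOYMENT_COLUMNS = ("tag_id", "age_class", "sex", "year",
                      "deploy_lat", "deploy_lon", "burst_interval_s")
TOWER_COLUMNS = ("recv_id", "lat", "lon", "region")


class SchemaError(ValueError):
    """A file does not match its declared column schema."""


def _load_csv(path, required: Sequence[str],
              column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{path}: ignoring extra column(s) {extra}", stacklevel=3)
    return df[list(required)]


def _parse_ts(series: pd.Series, path, col: str = "ts") -> pd.Series:
    """ISO-8601 with explicit offset -> tz-aware UTC; name the bad line."""
    parsed = pd.to_datetime(series, errors="coerce", utc=True, format="ISO8601")
    bad = parsed.isna() | (series.str.strip() == "")
    # pd.to_datetime(utc=True) silently localizes naive strings; reject them
    naive = ~bad & ~series.str.contains(r"(?:Z|[+-]\d{2}:?\d{2})\s*$", regex=True)
    problem = bad | naive
    if problem.any():
        line = int(problem.idxmax()) + 2  # header is line 1
        raise SchemaError(
            f"{path}: unparseable or offset-less timestamp in column "
            f"'{col}' at line {line}: {series[problem.idxmax()]!r}")
    return parsed


def _parse_float(series: pd.Series, path, col: str) -> pd.Series:
    vals = pd.to_numeric(series, errors="coerce")
    if vals.isna().any() or not np.isfinite(vals.to_numpy(dtype=float)).all():
        line = int((~np.isfinite(pd.to_numeric(series, errors="coerce"))).idxmax()) + 2
        raise SchemaError(f"{path}: non-numeric/non-finite '{col}' at line {line}")
    return vals.astype(float)


def _parse_enum(series: pd.Series, allowed: Sequence[str], path, col: str) -> pd.Series:
    norm = series.str.strip().str.lower()
    bad = ~norm.isin(allowed)
    if bad.any():
        raise SchemaError(
            f"{path}: invalid {col} value(s) {sorted(series[bad].unique())}; "
            f"allowed: {list(allowed)}")
    return norm


# ---------------------------------------------------------------------------
# detections

def read_detections(path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a detection table; rows come back sorted by (tag_id, ts)."""
    df = _load_csv(path, DETECTION_COLUMNS, column_map)
    out = pd.DataFrame({
        "tag_id": df["tag_id"].astype(str),
        "ts": _parse_ts(df["ts"], path),
        "recv_id": df["recv_id"].astype(str),
        "sig": _parse_float(df["sig"], path, "sig"),
    })
    return out.sort_values(["tag_id", "ts"], kind="mergesort").reset_index(drop=True)


def write_detections(detections: pd.DataFrame, path) -> None:
    df = detections.copy()
    df["ts"] = pd.to_datetime(df["ts"], utc=True).dt.strftime("%Y-%m-%dT%H:%M:%S.%f")
    df["ts"] = df["ts"].str.slice(0, 23) + "Z"  # millisecond precision
    df[list(DETECTION_COLUMNS)].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# deployments / towers

def read_deployments(path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    df = _load_csv(path, DEPLOYMENT_COLUMNS, column_map)
    out = pd.DataFrame({
        "tag_id": df["tag_id"].astype(str),
        "age_class": _parse_enum(df["age_class"], AGE_CLASSES, path, "age_class"),
        "sex": _parse_enum(df["sex"], SEXES, path, "sex"),
        "year": _parse_float(df["year"], path, "year").astype(int),
        "deploy_lat": _parse_float(df["deploy_lat"], path, "deploy_lat"),
        "deploy_lon": _parse_float(df["deploy_lon"], path, "deploy_lon"),
        "burst_interval_s": _parse_float(df["burst_interval_s"], path, "burst_interval_s"),
    })
    if ((out["deploy_lat"].abs() > 90) | (out["deploy_lon"].abs() > 180)).any():
        raise SchemaError(f"{path}: coordinates outside WGS-84 bounds")
    if (out["burst_interval_s"] <= 0).any():
        raise SchemaError(f"{path}: burst_interval_s must be > 0")
    dup = out["tag_id"].duplicated()
    if dup.any():
        warnings.warn(
            f"{path}: duplicate tag_id(s) {sorted(out.loc[dup, 'tag_id'].unique())} "
            "(possible cross-project duplicate tags)", stacklevel=2)
    return out.reset_index(drop=True)


def write_deployments(deployments: pd.DataFrame, path) -> None:
    deployments[list(DEPLOYMENT_COLUMNS)].to_csv(path, index=False)


def read_towers(path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    df = _load_csv(path, TOWER_COLUMNS, column_map)
    out = pd.DataFrame({
        "recv_id": df["recv_id"].astype(str),
        "lat": _parse_float(df["lat"], path, "lat"),
        "lon": _parse_float(df["lon"], path, "lon"),
        "region": _parse_enum(df["region"], REGIONS, path, "region"),
    })
    if out["recv_id"].duplicated().any():
        raise SchemaError(f"{path}: duplicate recv_id")
    if ((out["lat"].abs() > 90) | (out["lon"].abs() > 180)).any():
        raise SchemaError(f"{path}: coordinates outside WGS-84 bounds")
    return out.reset_index(drop=True)


def write_towers(towers: pd.DataFrame, path) -> None:
    towers[list(TOWER_COLUMNS)].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# wind

@dataclass
class WindGrid:
    """Gridded u/v wind (m/s) on a single pressure level.

    Axes are strictly increasing; ``u``/``v`` are shaped
    (time, lat, lon).  u > 0 blows toward 090 deg (east), v > 0 toward
    000 deg (north).
    """

    times: pd.DatetimeIndex
    lats: np.ndarray
    lons: np.ndarray
    u: np.ndarray
    v: np.ndarray
    level: float = 925.0

    def __post_init__(self) -> None:
        self.times = pd.DatetimeIndex(self.times)
        if self.times.tz is None:
            raise ValueError("wind times must be timezone-aware (UTC)")
        self.times = self.times.tz_convert("UTC")
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        for name, ax in (("time", self.times.asi8), ("lat", self.lats), ("lon", self.lons)):
            if len(ax) > 1 and not np.all(np.diff(ax) > 0):
                raise ValueError(f"wind {name} axis not strictly increasing")
        shape = (len(self.times), len(self.lats), len(self.lons))
        if self.u.shape != shape or self.v.shape != shape:
            raise ValueError(f"u/v shape mismatch: expected {shape}")
        if not (np.isfinite(self.u).all() and np.isfinite(self.v).all()):
            raise ValueError("wind components must be finite")

    def __eq__(self, other) -> bool:  # type: ignore[override]
        return (isinstance(other, WindGrid)
                and self.times.equals(other.times)
                and np.array_equal(self.lats, other.lats)
                and np.array_equal(self.lons, other.lons)
                and np.allclose(self.u, other.u, atol=1e-9)
                and np.allclose(self.v, other.v, atol=1e-9)
                and self.level == other.level)

    def to_xarray(self):
        import xarray as xr
        return xr.Dataset(
            {"u": (("time", "lat", "lon"), self.u),
             "v": (("time", "lat", "lon"), self.v)},
            coords={"time": self.times.tz_localize(None),
                    "lat": self.lats, "lon": self.lons},
            attrs={"level": float(self.level)},
        )

    def to_frame(self) -> pd.DataFrame:
        t, la, lo = np.meshgrid(np.arange(len(self.times)), self.lats, self.lons,
                                indexing="ij")
        return pd.DataFrame({
            "ts": self.times[t.ravel()],
            "lat": la.ravel(), "lon": lo.ravel(),
            "level": self.level,
            "u": self.u.ravel(), "v": self.v.ravel(),
        })


def read_wind(path) -> WindGrid:
    """Read a wind grid from NetCDF or long-form CSV (dialects equivalent)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".nc", ".cdf", ".nc4"):
        return _read_wind_netcdf(path)
    return _read_wind_csv(path)


def _read_wind_netcdf(path) -> WindGrid:
    import xarray as xr
    ds = xr.open_dataset(path, engine="scipy")
    try:
        for var in ("u", "v"):
            if var not in ds:
                raise SchemaError(f"{path}: missing wind variable '{var}'")
        for coord in ("time", "lat", "lon"):
            if coord not in ds.coords:
                raise SchemaError(f"{path}: missing coordinate '{coord}'")
        ds = ds.sortby(["time", "lat", "lon"])
        times = pd.DatetimeIndex(ds["time"].values).tz_localize("UTC")
        return WindGrid(times=times,
                        lats=ds["lat"].values, lons=ds["lon"].values,
                        u=ds["u"].transpose("time", "lat", "lon").values,
                        v=ds["v"].transpose("time", "lat", "lon").values,
                        level=float(ds.attrs.get("level", 925.0)))
    finally:
        ds.close()


def _read_wind_csv(path) -> WindGrid:
    df = pd.read_csv(path)
    for col in ("ts", "lat", "lon", "level", "u", "v"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing wind column '{col}'")
    df["ts"] = _parse_ts(df["ts"].astype(str), path)
    df = df.sort_values(["ts", "lat", "lon"])
    times = pd.DatetimeIndex(sorted(df["ts"].unique()))
    lats = np.sort(df["lat"].unique())
    lons = np.sort(df["lon"].unique())
    if len(df) != len(times) * len(lats) * len(lons):
        raise SchemaError(f"{path}: wind CSV is not a complete time x lat x lon grid")
    shape = (len(times), len(lats), len(lons))
    u = df["u"].to_numpy(dtype=float).reshape(shape)
    v = df["v"].to_numpy(dtype=float).reshape(shape)
    return WindGrid(times=times, lats=lats, lons=lons, u=u, v=v,
                    level=float(df["level"].iloc[0]))


def write_wind(grid: WindGrid, path) -> None:
    """Write NetCDF for ``.nc``-style suffixes, long CSV otherwise."""
    path = Path(path)
    if path.suffix.lower() in (".nc", ".cdf", ".nc4"):
        grid.to_xarray().to_netcdf(path, engine="scipy")
    else:
        df = grid.to_frame()
        df["ts"] = df["ts"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
        df.to_csv(path, index=False)
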