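"""File formats: track CSV, ACC-burst CSV, segment CSV, daily-summary CSV and
the NetCDF wind grid.

Track CSVs mirror common bio-logging exports: one row per fix with bird_id,
ISO-8601 UTC timestamp, lon, lat and altitude above ground.  ACC bursts live
in a sibling CSV keyed by bird_id + timestamp with 114 sample columns
(surge_00..heave_37, g).  Wind grids are self-describing NetCDF with named
dimensions x/y/z/t and variables U, V, TKE.  Malformed rows are counted and
logged, never silently dropped.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .core import (AccBurst, FixSeries, FlightSegment, SchemaError,
                   IntegrityError, WindField, MODE_GLIDE)
from .metrics import DailySummary

log = logging.getLogger(__name__)

TRACK_COLUMNS = ["bird_id", "timestamp", "lon", "lat", "altitude_agl"]
ACC_AXES = ("surge", "sway", "heave")
ACC_SAMPLE_COLUMNS = [f"{ax}_{i:02d}" for ax in ACC_AXES for i in range(AccBurst.N_SAMPLES)]
SEGMENT_COLUMNS = [
    "bird_id", "mode", "start_idx", "end_idx", "start_time", "duration_s",
    "altitudinal_change_m", "travel_distance_m", "mean_vertical_speed_ms",
    "mean_horizontal_speed_ms", "mean_angular_speed_degs",
    "start_lon", "start_lat", "wind_support_ms", "side_wind_ms",
    "mean_airspeed_ms", "radius_m", "circling_dir",
    "wind_shear_ms", "shear_class", "tke_1km",
]


def _iso(times: np.ndarray) -> pd.Series:
    return pd.to_datetime(np.asarray(times, dtype=float), unit="s", utc=True).strftime(
        "%Y-%m-%dT%H:%M:%S.%f"
    )


def _from_iso(col: pd.Series) -> np.ndarray:
    dt = pd.to_datetime(col, utc=True, format="ISO8601")
    return dt.astype("int64").to_numpy() / 1e9


def write_track(path, series: FixSeries) -> None:
    df = series.df
    out = pd.DataFrame({
        "bird_id": df["bird_id"], "timestamp": _iso(df["time"].to_numpy()),
        "lon": df["lon"], "lat": df["lat"], "altitude_agl": df["altitude_agl"],
    })
    out.to_csv(path, index=False)


def read_track(path, origin: Optional[tuple[float, float]] = None) -> FixSeries:
    """Read a per-fix track CSV into a typed, time-sorted series.

    Rows with unparseable/missing mandatory values are counted and logged;
    out-of-range values (|lat| > 90, non-finite altitude) and non-monotone
    timestamps are integrity errors.
    """
    raw = pd.read_csv(path, dtype={"bird_id": str})
    missing = set(TRACK_COLUMNS) - set(raw.columns)
    if missing:
        raise SchemaError(f"track file missing mandatory column(s): {sorted(missing)}")
    time = pd.to_datetime(raw["timestamp"], utc=True, errors="coerce", format="mixed")
    num = raw[["lon", "lat", "altitude_agl"]].apply(pd.to_numeric, errors="coerce")
    bad = time.isna() | num.isna().any(axis=1)
    if bad.any():
        log.warning("dropped %d malformed track rows from %s", int(bad.sum()), path)
    df = pd.DataFrame({
        "bird_id": raw["bird_id"],
        "time": time.astype("int64").to_numpy() / 1e9,
        "lon": num["lon"], "lat": num["lat"], "altitude_agl": num["altitude_agl"],
    }).loc[~bad].reset_index(drop=True)
    return FixSeries.from_fixes(df, origin=origin)


def write_acc(path, bursts: Sequence[AccBurst]) -> None:
    rows = []
    for b in bursts:
        row = {"bird_id": b.bird_id, "timestamp": _iso(np.array([b.time]))[0]}
        for a, ax in enumerate(ACC_AXES):
            for i in range(AccBurst.N_SAMPLES):
                row[f"{ax}_{i:02d}"] = b.samples[a, i]
        rows.append(row)
    pd.DataFrame(rows, columns=["bird_id", "timestamp"] + ACC_SAMPLE_COLUMNS).to_csv(
        path, index=False
    )


def read_acc(path) -> list[AccBurst]:
    raw = pd.read_csv(path, dtype={"bird_id": str})
    missing = set(["bird_id", "timestamp"] + ACC_SAMPLE_COLUMNS) - set(raw.columns)
    if missing:
        raise SchemaError(f"ACC file missing column(s): {sorted(list(missing))[:5]} ...")
    times = _from_iso(raw["timestamp"])
    sample_mat = raw[ACC_SAMPLE_COLUMNS].to_numpy(dtype=float)
    bursts = []
    n_bad = 0
    for i in range(len(raw)):
        samples = sample_mat[i].reshape(3, AccBurst.N_SAMPLES)
        if not np.all(np.isfinite(samples)):
            n_bad += 1
            continue
        bursts.append(AccBurst(bird_id=raw["bird_id"].iloc[i], time=times[i], samples=samples))
    if n_bad:
        log.warning("dropped %d malformed ACC bursts from %s", n_bad, path)
    bursts.sort(key=lambda b: (b.bird_id, b.time))
    return bursts


def write_segments(path, segments: Sequence[FlightSegment]) -> None:
    """One row per segment; wind support/side-wind populated for glides only.

    Overlapping segments of one bird are rejected.
    """
    by_bird: dict[str, list[FlightSegment]] = {}
    for s in segments:
        by_bird.setdefault(s.bird_id, []).append(s)
    for bird, segs in by_bird.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs[:-1], segs[1:]):
            if b.start < a.end:
                raise IntegrityError(f"overlapping segments for bird {bird}")
    rows = []
    for s in sorted(segments, key=lambda s: (s.bird_id, s.start)):
        is_glide = s.mode == MODE_GLIDE
        rows.append({
            "bird_id": s.bird_id, "mode": s.mode,
            "start_idx": s.start, "end_idx": s.end,
            "start_time": _iso(np.array([s.start_time]))[0] if np.isfinite(s.start_time) else "",
            "duration_s": s.duration,
            "altitudinal_change_m": s.altitudinal_change,
            "travel_distance_m": s.travel_distance,
            "mean_vertical_speed_ms": s.mean_vertical_speed,
            "mean_horizontal_speed_ms": s.mean_horizontal_speed,
            "mean_angular_speed_degs": s.mean_angular_speed,
            "start_lon": s.start_lon, "start_lat": s.start_lat,
            "wind_support_ms": s.wind_support if is_glide else np.nan,
            "side_wind_ms": s.side_wind if is_glide else np.nan,
            "mean_airspeed_ms": s.mean_airspeed,
            "radius_m": s.radius_m, "circling_dir": s.circling_dir,
            "wind_shear_ms": s.wind_shear, "shear_class": s.shear_class,
            "tke_1km": s.tke_1km,
        })
    pd.DataFrame(rows, columns=SEGMENT_COLUMNS).to_csv(path, index=False)


def read_segments(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"bird_id": str, "mode": str})
    missing = set(SEGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"segment file missing column(s): {sorted(missing)}")
    return df


def write_daily_summary(path, days: Sequence[DailySummary]) -> None:
    pd.DataFrame([vars(d) for d in days]).to_csv(path, index=False)


def write_wind_grid(path, fld: WindField) -> None:
    fld.ds.to_netcdf(path, engine="scipy")


def read_wind_grid(path) -> WindField:
    """Read a NetCDF wind grid; missing variables or non-monotone axes fail
    with the offending name."""
    with xr.open_dataset(path, engine="scipy") as ds:
        return WindField(ds.load())
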