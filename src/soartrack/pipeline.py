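"""End-to-end orchestration: simulate/read -> preprocess -> annotate ->
segment -> metrics -> stats, with a reproducible manifest.

Every stage is a pure function of its inputs plus the config; re-running
with the same config (and seed) writes bit-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .core import FixSeries, FlightSegment, MODE_THERMAL
from .metrics import (DailySummary, GlidePolar, circling_radius, climb_rate,
                      daily_summary, foraging_day_filter, rafi,
                      thermal_glide_pairs, thermal_selection_tke)
from .preprocess import classify_bursts, compute_odba, detect_flight, smooth_vertical_speed
from .segmentation import segment_track
from .stats import bin_climb_difference, fit_shear_models, model_table, mww_test
from .synthetic import SyntheticTrack, extent_for_series, simulate_track, simulate_wind_field
from .track_io import (read_acc, read_track, read_wind_grid,
                       write_daily_summary, write_segments)
from .wind import annotate_series, wind_shear_class

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    series: FixSeries
    bursts: list
    segments: list[FlightSegment]
    days: list[DailySummary]
    pairs: pd.DataFrame
    thermal_table: pd.DataFrame
    stats_tables: dict
    manifest: dict
    truth: Optional[SyntheticTrack] = None


def _annotate_by_day(series: FixSeries, config: PipelineConfig,
                     track: Optional[SyntheticTrack]) -> None:
    """Annotate fixes with wind day by day (keeps per-day grids small)."""
    df = series.df
    days = series.day_key().to_numpy()
    df["wind_u"] = np.nan
    df["wind_v"] = np.nan
    df["tke_1km"] = np.nan
    from .wind import _interp_arrays

    sim = replace(config.simulation, seed=config.seed)
    for day in pd.unique(days):
        idx = np.nonzero(days == day)[0]
        sub = FixSeries(df=df.iloc[idx].reset_index(drop=True), origin=series.origin)
        fld = simulate_wind_field(sim, extent_for_series(sub))
        u, v, tke = _interp_arrays(
            fld, df["lon"].to_numpy()[idx], df["lat"].to_numpy()[idx],
            df["altitude_agl"].to_numpy()[idx], df["time"].to_numpy()[idx],
        )
        df.loc[df.index[idx], "wind_u"] = u
        df.loc[df.index[idx], "wind_v"] = v
        df.loc[df.index[idx], "tke_1km"] = tke


def run_pipeline(
    config: PipelineConfig,
    input_track: Optional[str] = None,
    input_acc: Optional[str] = None,
    input_wind: Optional[str] = None,
    write_outputs: bool = True,
) -> PipelineResult:
    """Run the full analysis; simulate inputs when no files are given."""
    out_dir = Path(config.out_dir)
    if write_outputs:
        out_dir.mkdir(parents=True, exist_ok=True)

    truth = None
    if input_track is None:
        sim = replace(config.simulation, seed=config.seed)
        truth = simulate_track(sim)
        series, bursts = truth.series, truth.bursts
    else:
        series = read_track(input_track)
        bursts = read_acc(input_acc) if input_acc else []

    detect_flight(series, config.flight.speed_threshold_ms)
    smooth_vertical_speed(series, config=config.smooth)
    for b in bursts:
        compute_odba(b)
    classify_bursts(bursts, config.acc)

    if input_wind is not None:
        annotate_series(series, read_wind_grid(input_wind))
    else:
        _annotate_by_day(series, config, truth)

    segments = segment_track(series, config.seg)

    thermal_rows = []
    for s in segments:
        if s.mode != MODE_THERMAL:
            continue
        try:
            ctx = wind_shear_class(s, series, config=config.wind)
            s.wind_shear, s.shear_class = ctx.wind_shear, ctx.shear_class
        except ValueError:
            pass
        try:
            s.radius_m = circling_radius(s, series)
        except ValueError as e:
            log.info("thermal at %d: radius undefined (%s)", s.start, e)
        try:
            s.tke_1km = thermal_selection_tke(s, series)
        except ValueError:
            pass
        thermal_rows.append({
            "start_idx": s.start, "start_time": s.start_time,
            "duration_s": s.duration, "climb_rate": climb_rate(s, series),
            "radius_m": s.radius_m, "wind_shear": s.wind_shear,
            "shear_class": s.shear_class, "tke_1km": s.tke_1km,
        })
    thermal_table = pd.DataFrame(thermal_rows)

    pairs = thermal_glide_pairs(segments, series, config.metrics.pair_max_gap_s)
    polar = GlidePolar.from_config(config.polar)
    seg_by_start = {s.start: s for s in segments}
    rafi_vals = []
    for _, row in pairs.iterrows():
        try:
            rafi_vals.append(rafi(seg_by_start[int(row["glide_start"])],
                                  row["climb_rate"], polar,
                                  config.metrics.rafi_definition))
        except ValueError:
            rafi_vals.append(np.nan)
    if len(pairs):
        pairs = pairs.assign(rafi=rafi_vals)

    days = daily_summary(series, segments, bursts, config.metrics)
    for d in days:
        foraging_day_filter(d, config.filter)
    foraging_days = [d for d in days if d.is_foraging_day]
    if not foraging_days:
        log.warning("no days pass the foraging filter; stats tables will be empty")

    stats_tables = _run_stats(thermal_table, config)

    manifest = {
        "package": "soartrack", "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "n_fixes": len(series), "n_bursts": len(bursts),
        "n_segments": len(segments), "n_days": len(days),
        "n_foraging_days": len(foraging_days),
    }

    if write_outputs:
        write_segments(out_dir / "segments.csv", segments)
        write_daily_summary(out_dir / "daily_summary.csv", days)
        thermal_table.to_csv(out_dir / "thermals.csv", index=False)
        pairs.to_csv(out_dir / "pairs.csv", index=False)
        for name, tbl in stats_tables.items():
            tbl.to_csv(out_dir / f"stats_{name}.csv", index=False)
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    return PipelineResult(
        series=series, bursts=bursts, segments=segments, days=days,
        pairs=pairs, thermal_table=thermal_table, stats_tables=stats_tables,
        manifest=manifest, truth=truth,
    )


def _run_stats(thermal_table: pd.DataFrame, config: PipelineConfig) -> dict:
    """Age-class comparisons when an age_class column is present; otherwise a
    descriptive summary only (single-class data cannot be compared)."""
    tables: dict[str, pd.DataFrame] = {}
    if thermal_table.empty:
        return tables
    tables["thermal_summary"] = thermal_table[["climb_rate", "radius_m", "wind_shear"]].agg(
        ["mean", "std", "count"]
    ).reset_index(names="stat")
    if "age_class" in thermal_table.columns and thermal_table["age_class"].nunique() == 2:
        ad = thermal_table.loc[thermal_table["age_class"] == "adult", "climb_rate"]
        ju = thermal_table.loc[thermal_table["age_class"] == "juvenile", "climb_rate"]
        cmp_ = mww_test(ad, ju)
        tables["climb_mww"] = pd.DataFrame([{
            "U": cmp_.statistic, "p": cmp_.p_value,
            "adult_mean": cmp_.group_means["x"], "juvenile_mean": cmp_.group_means["y"],
        }])
        bins = bin_climb_difference(
            thermal_table.rename(columns={"wind_shear": "wind_shear"}),
            config.stats.shear_bin_width, config.stats,
        )
        if len(bins) >= 4:
            fits, selected = fit_shear_models(bins["shear"], bins["difference"])
            tbl = model_table(fits)
            tbl["selected"] = [f.model == selected.model for f in fits]
            tables["shear_models"] = tbl
            tables["shear_bins"] = bins
    return tables
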