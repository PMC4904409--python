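"""Flight-performance metrics.

Per-thermal: climb rate, drift-compensated circling radius, 1-km TKE.
Per-glide: airspeed choice relative to the glide polar (best-glide and
MacCready reference speeds, risk-aversion index).  Per-pair: soaring-gliding
efficiency.  Per-day: path statistics, flapping proportion, ODBA and the
foraging-trip filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .config import FilterConfig, MetricsConfig, PolarConfig
from .core import (AccBurst, FixSeries, FlightSegment, WindVector,
                   MODE_GLIDE, MODE_LINEAR, MODE_THERMAL)
from .segmentation import characterize_segment

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# thermal metrics


def climb_rate(thermal: FlightSegment, series: FixSeries) -> float:
    """Net altitude gained per second over the thermal (m/s)."""
    if np.isnan(thermal.duration):
        characterize_segment(thermal, series)
    if thermal.altitudinal_change <= 0:
        raise ValueError("thermal must gain altitude; not a valid thermal segment")
    return thermal.altitudinal_change / thermal.duration


def _kasa_circle(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Algebraic least-squares circle fit plus one Gauss-Newton refinement."""
    A = np.column_stack([x, y, np.ones_like(x)])
    b = x**2 + y**2
    (cx2, cy2, c), *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy = cx2 / 2.0, cy2 / 2.0
    r = float(np.sqrt(max(c + cx**2 + cy**2, 0.0)))
    # one geometric refinement step on (cx, cy, r)
    for _ in range(1):
        dx, dy = x - cx, y - cy
        di = np.hypot(dx, dy)
        di = np.where(di > 1e-12, di, 1e-12)
        J = np.column_stack([-dx / di, -dy / di, -np.ones_like(di)])
        resid = di - r
        step, *_ = np.linalg.lstsq(J, -resid, rcond=None)
        cx, cy, r = cx + step[0], cy + step[1], r + step[2]
    return float(cx), float(cy), float(r)


def _segment_wind_arrays(thermal: FlightSegment, series: FixSeries,
                         wind: Optional[WindVector]):
    df = series.df
    a, b = thermal.start, thermal.end
    if wind is not None:
        u = np.full(b - a, wind.u)
        v = np.full(b - a, wind.v)
    elif "wind_u" in df.columns:
        u = df["wind_u"].to_numpy()[a:b]
        v = df["wind_v"].to_numpy()[a:b]
    else:
        raise ValueError("no wind annotation available for drift compensation")
    return u, v


def _drift_compensated(thermal: FlightSegment, series: FixSeries,
                       wind: Optional[WindVector]):
    df = series.df
    a, b = thermal.start, thermal.end
    t = df["time"].to_numpy()[a:b]
    x = df["x"].to_numpy()[a:b]
    y = df["y"].to_numpy()[a:b]
    u, v = _segment_wind_arrays(thermal, series, wind)
    dt = np.r_[0.0, np.diff(t)]
    drift = np.stack([np.cumsum(u * dt), np.cumsum(v * dt)], axis=1)
    pos = np.stack([x, y], axis=1)
    return pos - drift, drift, t


def _loop_bounds(thermal: FlightSegment, series: FixSeries) -> list[tuple[int, int]]:
    """Split the event into full 360-degree loops (segment-local indices)."""
    heads = series.df["heading"].to_numpy()[thermal.start + 1:thermal.end]
    if len(heads) < 3:
        return []
    dh = np.diff(heads)
    dh = (dh + 180.0) % 360.0 - 180.0
    cum = np.abs(np.cumsum(dh))
    bounds = []
    start = 0
    turned = 0.0
    for i, c in enumerate(cum):
        if c - turned >= 360.0:
            bounds.append((start, i + 2))  # local fix index range, inclusive end
            turned = c
            start = i + 1
    return bounds


def circling_radius(
    thermal: FlightSegment,
    series: FixSeries,
    wind: Optional[WindVector] = None,
) -> float:
    """Mean per-loop circle-fit radius after subtracting cumulative wind drift.

    Requires at least one full loop; raises ValueError otherwise.
    """
    pos, _, _ = _drift_compensated(thermal, series, wind)
    loops = _loop_bounds(thermal, series)
    if not loops:
        raise ValueError("circling radius undefined: less than one full loop")
    radii = []
    for a, b in loops:
        if b - a >= 5:
            _, _, r = _kasa_circle(pos[a:b, 0], pos[a:b, 1])
            radii.append(r)
    if not radii:
        raise ValueError("no loop had enough fixes for a circle fit")
    return float(np.mean(radii))


def thermal_center_trajectory(
    thermal: FlightSegment,
    series: FixSeries,
    wind: Optional[WindVector] = None,
) -> np.ndarray:
    """Per-fix position of the drifting thermal column centre.

    The circle centre fitted in drift-compensated coordinates, re-advected by
    the cumulative wind drift.
    """
    pos, drift, _ = _drift_compensated(thermal, series, wind)
    cx, cy, _ = _kasa_circle(pos[:, 0], pos[:, 1])
    return np.array([cx, cy]) + drift


def thermal_selection_tke(
    thermal: FlightSegment,
    series: FixSeries,
    fld=None,
) -> float:
    """Mean 1-km-scale TKE along the thermal (J/kg)."""
    df = series.df
    a, b = thermal.start, thermal.end
    if "tke_1km" in df.columns and np.all(np.isfinite(df["tke_1km"].to_numpy()[a:b])):
        return float(np.mean(df["tke_1km"].to_numpy()[a:b]))
    if fld is None:
        raise ValueError("series not annotated and no wind field given")
    from .wind import _interp_arrays

    _, _, tke = _interp_arrays(
        fld, df["lon"].to_numpy()[a:b], df["lat"].to_numpy()[a:b],
        df["altitude_agl"].to_numpy()[a:b], df["time"].to_numpy()[a:b],
    )
    return float(np.mean(tke))


# ---------------------------------------------------------------------------
# glide polar and airspeed-choice metrics


@dataclass
class GlidePolar:
    """Quadratic glide polar sink(v) = a v^2 + b v + c (m/s, sink > 0 down)."""

    a: float
    b: float = 0.0
    c: float = 1.0
    v_range: tuple[float, float] = (6.0, 30.0)

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError("polar curvature a must be > 0")
        v = np.linspace(*self.v_range, 50)
        if np.any(self.sink(v) <= 0):
            raise ValueError("sink must be positive over the valid airspeed range")

    @classmethod
    def from_config(cls, cfg: PolarConfig) -> "GlidePolar":
        return cls(a=cfg.a, b=cfg.b, c=cfg.c, v_range=tuple(cfg.v_range))

    def sink(self, v):
        return self.a * np.asarray(v, dtype=float) ** 2 + self.b * np.asarray(v) + self.c


def best_glide_speed(polar: GlidePolar) -> float:
    """Airspeed maximizing glide ratio v / sink(v); closed form sqrt(c/a) at b=0."""
    lo, hi = polar.v_range
    if polar.b == 0.0:
        v = float(np.sqrt(polar.c / polar.a))
        return float(np.clip(v, lo, hi))
    res = minimize_scalar(lambda v: polar.sink(v) / v, bounds=(lo, hi), method="bounded")
    return float(res.x)


def maccready_speed(polar: GlidePolar, climb_expected: float) -> float:
    """Time-optimal inter-thermal airspeed for an expected climb rate.

    Maximizes cross-country speed v * z / (z + sink(v)); closed form
    sqrt((c + z)/a) when b = 0.  Negative expected climb clamps to 0.
    """
    z = climb_expected
    if z < 0:
        log.info("negative expected climb %.3f clamped to 0", z)
        z = 0.0
    lo, hi = polar.v_range
    if polar.b == 0.0:
        v = float(np.sqrt((polar.c + z) / polar.a))
        return float(np.clip(v, lo, hi))
    res = minimize_scalar(
        lambda v: -(v * z / (z + polar.sink(v))) if z > 0 else polar.sink(v) / v,
        bounds=(lo, hi), method="bounded",
    )
    return float(res.x)


def rafi(
    glide: FlightSegment,
    preceding_climb: float,
    polar: GlidePolar,
    definition: str = "normalized",
) -> float:
    """Risk-aversion index of one glide's observed airspeed.

    "normalized" (default): (V_mc - V_obs) / (V_mc - V_bg) clipped to
    [0, 1.2]; 1 = best-glide (risk-averse), 0 = MacCready (risk-prone).
    "ratio": V_bg / V_obs.
    """
    v_obs = glide.mean_airspeed
    if not np.isfinite(v_obs) or v_obs <= 0:
        raise ValueError("glide has no mean airspeed; annotate wind first")
    v_bg = best_glide_speed(polar)
    if definition == "ratio":
        return float(v_bg / v_obs)
    v_mc = maccready_speed(polar, preceding_climb)
    if abs(v_mc - v_bg) < 1e-9:
        raise ValueError("RAFI undefined: MacCready equals best-glide (zero climb)")
    return float(np.clip((v_mc - v_obs) / (v_mc - v_bg), 0.0, 1.2))


# ---------------------------------------------------------------------------
# pairing and daily metrics


def thermal_glide_pairs(
    segments: Sequence[FlightSegment],
    series: FixSeries,
    max_gap_s: float = 10.0,
) -> pd.DataFrame:
    """Thermal -> immediately-following glide pairs and their efficiency.

    Efficiency of a pair is the glide's travel distance divided by the
    preceding thermal-soaring duration (m per s of climb).
    """
    t = series.df["time"].to_numpy()
    segs = sorted(segments, key=lambda s: s.start)
    rows = []
    for prev, nxt in zip(segs[:-1], segs[1:]):
        if prev.mode == MODE_THERMAL and nxt.mode == MODE_GLIDE:
            gap = t[nxt.start] - t[prev.end - 1]
            if gap <= max_gap_s:
                if np.isnan(prev.duration):
                    characterize_segment(prev, series)
                if np.isnan(nxt.duration):
                    characterize_segment(nxt, series)
                rows.append({
                    "thermal_start": prev.start, "glide_start": nxt.start,
                    "thermal_duration": prev.duration,
                    "glide_distance": nxt.travel_distance,
                    "climb_rate": prev.altitudinal_change / prev.duration,
                    "efficiency": nxt.travel_distance / prev.duration,
                    "time": t[prev.start],
                })
    return pd.DataFrame(rows)


def soaring_gliding_efficiency(
    segments: Sequence[FlightSegment],
    series: FixSeries,
    max_gap_s: float = 10.0,
) -> float:
    """Mean glide-distance / preceding-climb-duration over qualifying pairs."""
    pairs = thermal_glide_pairs(segments, series, max_gap_s)
    if pairs.empty:
        raise ValueError("no qualifying thermal-glide pairs")
    return float(pairs["efficiency"].mean())


@dataclass
class DailySummary:
    """Per-bird-day path and energy metrics."""

    bird_id: str
    date: str
    travel_distance_km: float
    max_displacement_km: float
    straightness: float
    flapping_proportion: float
    mean_odba: float
    n_thermals: int
    n_glides: int
    n_linear: int
    soaring_gliding_efficiency: float
    roost_distance_km: float
    is_foraging_day: Optional[bool] = None


def daily_summary(
    series: FixSeries,
    segments: Sequence[FlightSegment],
    bursts: Sequence[AccBurst],
    config: Optional[MetricsConfig] = None,
    roost_xy: tuple[float, float] = (0.0, 0.0),
) -> list[DailySummary]:
    """Daily path, mode-count, flapping and ODBA metrics for one bird.

    Straightness is maximum displacement divided by the travel distance
    accumulated up to (and including) the fix of maximum displacement.
    """
    cfg = config or MetricsConfig()
    df = series.df
    days = series.day_key().to_numpy()
    t = df["time"].to_numpy()
    out = []
    for day in pd.unique(days):
        m = days == day
        idx = np.nonzero(m)[0]
        if len(idx) < 2:
            log.info("day %s skipped: fewer than 2 fixes", day)
            continue
        x = df["x"].to_numpy()[idx]
        y = df["y"].to_numpy()[idx]
        steps = np.hypot(np.diff(x), np.diff(y))
        travel = steps.sum()
        disp = np.hypot(x - x[0], y - y[0])
        k = int(np.argmax(disp))
        max_disp = disp[k]
        travel_until = steps[:k].sum()
        straightness = float(max_disp / travel_until) if travel_until > 0 else 1.0
        straightness = min(straightness, 1.0)

        t_lo, t_hi = t[idx[0]], t[idx[-1]]
        day_bursts = [b for b in bursts if t_lo <= b.time <= t_hi]
        flight_bursts = [b for b in day_bursts if _burst_in_flight(b, series)]
        n_flap = sum(1 for b in flight_bursts if b.flap_label == "flapping")
        flap_prop = n_flap / len(flight_bursts) if flight_bursts else 0.0
        odbas = [b.odba for b in flight_bursts if b.odba is not None]
        mean_odba = float(np.mean(odbas)) if odbas else np.nan

        day_segs = [s for s in segments if t_lo <= s.start_time <= t_hi]
        try:
            eff = soaring_gliding_efficiency(day_segs, series, cfg.pair_max_gap_s)
        except ValueError:
            eff = np.nan
            log.info("day %s: no qualifying thermal-glide pairs", day)

        out.append(DailySummary(
            bird_id=series.bird_id, date=str(day),
            travel_distance_km=float(travel / 1000.0),
            max_displacement_km=float(max_disp / 1000.0),
            straightness=straightness,
            flapping_proportion=float(flap_prop),
            mean_odba=mean_odba,
            n_thermals=sum(1 for s in day_segs if s.mode == MODE_THERMAL),
            n_glides=sum(1 for s in day_segs if s.mode == MODE_GLIDE),
            n_linear=sum(1 for s in day_segs if s.mode == MODE_LINEAR),
            soaring_gliding_efficiency=float(eff),
            roost_distance_km=float(np.hypot(x[0] - roost_xy[0], y[0] - roost_xy[1]) / 1000.0),
        ))
    return out


def _burst_in_flight(burst: AccBurst, series: FixSeries) -> bool:
    if "in_flight" not in series.df.columns:
        return True
    t = series.df["time"].to_numpy()
    i = int(np.clip(np.searchsorted(t, burst.time) - 1, 0, len(t) - 1))
    return bool(series.df["in_flight"].to_numpy()[i])


def foraging_day_filter(day: DailySummary, config: Optional[FilterConfig] = None) -> bool:
    """Keep foraging days: short enough, tortuous enough, near the roost."""
    cfg = config or FilterConfig()
    flag = (
        day.travel_distance_km <= cfg.max_travel_km
        and day.straightness <= cfg.max_straightness
        and day.roost_distance_km <= cfg.roost_km
    )
    day.is_foraging_day = bool(flag)
    return day.is_foraging_day
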