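"""Two-stage flight-mode segmentation.

Stage 1 finds thermal-soaring events as chains of 2-D path self-intersections
(circling crosses its own recent path); an event qualifies as a thermal when
it lasts longer than 45 s and gains altitude.  Stage 2 partitions the
remaining in-flight track into gliding (descending) and linear-soaring
(climbing) runs in which at least 90% of smoothed vertical-speed samples
share the same sign, then trims run edges while doing so raises the in-trend
fraction.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np

from .config import SegConfig
from .core import (FixSeries, FlightSegment, WindVector,
                   MODE_GLIDE, MODE_LINEAR, MODE_THERMAL)
from .preprocess import contiguous_stretches

log = logging.getLogger(__name__)


def _self_intersection_spans(x: np.ndarray, y: np.ndarray, lookback: int) -> list[tuple[int, int]]:
    """For each step i, the earliest step j (i-lookback <= j <= i-2) whose
    segment properly intersects step i's segment; returned as fix-index
    intervals [j-1, i] covering both crossing steps."""
    n = len(x)
    if n < 4:
        return []
    earliest = np.full(n, -1, dtype=int)
    ax, ay = x[:-1], y[:-1]
    bx, by = x[1:], y[1:]  # step s spans fixes (s, s+1)
    n_steps = n - 1

    def cross(ox, oy, px, py, qx, qy):
        return (px - ox) * (qy - oy) - (py - oy) * (qx - ox)

    for d in range(2, min(lookback, n_steps - 1) + 1):
        s = np.arange(d, n_steps)  # current step index; earlier step s-d
        p1x, p1y, p2x, p2y = ax[s], ay[s], bx[s], by[s]
        q1x, q1y, q2x, q2y = ax[s - d], ay[s - d], bx[s - d], by[s - d]
        d1 = cross(p1x, p1y, p2x, p2y, q1x, q1y)
        d2 = cross(p1x, p1y, p2x, p2y, q2x, q2y)
        d3 = cross(q1x, q1y, q2x, q2y, p1x, p1y)
        d4 = cross(q1x, q1y, q2x, q2y, p2x, p2y)
        hit = (d1 * d2 < 0) & (d3 * d4 < 0)
        if hit.any():
            i_fix = s[hit] + 1  # later fix of current step
            j_fix = s[hit] - d  # earlier fix of the crossed step
            cur = earliest[i_fix]
            earliest[i_fix] = np.where(cur < 0, j_fix, np.minimum(cur, j_fix))
    return [(int(earliest[i]), int(i)) for i in np.nonzero(earliest >= 0)[0]]


def _merge_spans(spans: list[tuple[int, int]], times: np.ndarray,
                 merge_gap_s: float) -> list[tuple[int, int]]:
    if not spans:
        return []
    spans = sorted(spans)
    merged = [list(spans[0])]
    for a, b in spans[1:]:
        if times[a] - times[merged[-1][1]] <= merge_gap_s:
            merged[-1][1] = max(merged[-1][1], b)
            merged[-1][0] = min(merged[-1][0], a)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def detect_thermals(
    series: FixSeries,
    min_duration: float = 45.0,
    lookback: float = 120.0,
    config: Optional[SegConfig] = None,
) -> list[FlightSegment]:
    """Thermal-soaring segments from 2-D path self-intersection chains.

    Works per contiguous in-flight stretch; events closer than
    ``merge_gap_s`` merge (successive circles of one climb intersect
    repeatedly).  An event is a thermal iff it lasts more than
    ``min_duration`` seconds and its net altitude change is positive.
    """
    cfg = config or SegConfig(min_thermal_s=min_duration, lookback_s=lookback)
    df = series.df
    t = df["time"].to_numpy(dtype=float)
    alt = df["altitude_agl"].to_numpy(dtype=float)
    out: list[FlightSegment] = []
    for i0, i1 in contiguous_stretches(series, in_flight_only=True):
        if t[i1 - 1] - t[i0] < cfg.min_thermal_s:
            continue
        spans = _self_intersection_spans(
            df["x"].to_numpy()[i0:i1], df["y"].to_numpy()[i0:i1],
            int(round(cfg.lookback_s)),
        )
        for a, b in _merge_spans(spans, t[i0:i1], cfg.merge_gap_s):
            ga, gb = _trim_thermal_edges(series, i0 + a, i0 + b)
            duration = t[gb] - t[ga]
            if duration > cfg.min_thermal_s and alt[gb] - alt[ga] > 0:
                out.append(FlightSegment(mode=MODE_THERMAL, start=ga, end=gb + 1,
                                         bird_id=series.bird_id))
    return out


def _trim_thermal_edges(series: FixSeries, a: int, b: int) -> tuple[int, int]:
    """Shrink a candidate circling event to its turning core.

    Self-intersection chains reach a few seconds into the straight entry and
    exit legs (the circling path crosses them); in the same spirit as the
    trend-segment edge trimming, edge fixes whose turning rate falls below
    half the event's median turning rate are dropped.
    """
    from scipy.ndimage import uniform_filter1d

    heads = series.df["heading"].to_numpy()
    if b - a < 6:
        return a, b
    dh = (np.diff(heads) + 180.0) % 360.0 - 180.0  # signed turn entering fix i+1
    # centred 5-s mean of the signed turn: heading noise averages out while
    # sustained circling keeps its full rate
    sdh = np.abs(uniform_filter1d(dh, size=5, mode="nearest"))
    turn = sdh[a:b]
    thresh = np.median(turn) / 2.0
    lo, hi = a, b
    while hi - lo > 5 and sdh[lo] < thresh:
        lo += 1
    while hi - lo > 5 and sdh[hi - 1] < thresh:
        hi -= 1
    return lo, hi


def _trend_fraction(sgn: np.ndarray, trend: int) -> float:
    informative = sgn != 0
    if not informative.any():
        return 0.0
    return float((sgn == trend).sum() / informative.sum())


def detect_trend_segments(
    series: FixSeries,
    thermals: Sequence[FlightSegment],
    trend_fraction: float = 0.9,
    min_duration: float = 10.0,
    config: Optional[SegConfig] = None,
) -> list[FlightSegment]:
    """Gliding / linear-soaring runs outside thermals.

    Scans each non-thermal in-flight run for maximal stretches in which at
    least ``trend_fraction`` of smoothed vertical-speed samples share one
    sign (zeros count toward neither trend); descending runs become glides,
    ascending ones linear soaring.  Edges are trimmed with
    :func:`trim_segment_edges`; runs shorter than ``min_duration`` seconds
    are discarded.
    """
    cfg = config or SegConfig(trend_fraction=trend_fraction, min_trend_s=min_duration)
    df = series.df
    if "vspeed_smooth" not in df:
        raise ValueError("run smooth_vertical_speed first")
    t = df["time"].to_numpy(dtype=float)
    sgn = np.sign(df["vspeed_smooth"].to_numpy(dtype=float)).astype(int)

    blocked = np.zeros(len(df), dtype=bool)
    for th in thermals:
        blocked[th.start:th.end] = True

    out: list[FlightSegment] = []
    for s0, s1 in contiguous_stretches(series, in_flight_only=True):
        # sub-runs of the stretch not claimed by thermals
        i = s0
        while i < s1:
            if blocked[i]:
                i += 1
                continue
            j = i
            while j < s1 and not blocked[j]:
                j += 1
            out.extend(_scan_run(series, t, sgn, i, j, cfg))
            i = j
    return out


def _scan_run(series, t, sgn, lo, hi, cfg: SegConfig) -> list[FlightSegment]:
    """Greedy maximal trend runs inside [lo, hi)."""
    horizon = 300  # look-ahead budget (s) before declaring a run unrecoverable
    out = []
    i = lo
    while i < hi:
        if sgn[i] == 0:
            i += 1
            continue
        trend = sgn[i]
        n_same = 0
        n_opp = 0
        last_valid = -1
        j = i
        while j < hi:
            if sgn[j] == trend:
                n_same += 1
            elif sgn[j] != 0:
                n_opp += 1
            tot = n_same + n_opp
            frac = n_same / tot if tot else 1.0
            if frac >= cfg.trend_fraction:
                last_valid = j
            elif (n_same + horizon) / (tot + horizon) < cfg.trend_fraction:
                # even a solid in-trend stretch ahead could not restore the
                # threshold — stop extending
                break
            j += 1
        if last_valid < 0:
            i += 1
            continue
        seg = FlightSegment(
            mode=MODE_GLIDE if trend < 0 else MODE_LINEAR,
            start=i, end=last_valid + 1, bird_id=series.bird_id,
        )
        seg = trim_segment_edges(seg, series, min_duration=cfg.min_trend_s)
        if seg is not None and t[seg.end - 1] - t[seg.start] >= cfg.min_trend_s:
            out.append(seg)
        i = last_valid + 1
    return out


def trim_segment_edges(
    segment: FlightSegment,
    series: FixSeries,
    min_duration: float = 10.0,
) -> Optional[FlightSegment]:
    """Greedily trim segment edges while the in-trend fraction increases.

    At each step the first or last sample — whichever removal raises the
    fraction of samples matching the segment's trend more — is dropped, as
    long as some single-sample removal strictly increases the fraction.
    Returns None when trimming shrinks the segment below ``min_duration``.
    """
    trend = -1 if segment.mode == MODE_GLIDE else 1
    sgn = np.sign(series.df["vspeed_smooth"].to_numpy(dtype=float)).astype(int)
    t = series.df["time"].to_numpy(dtype=float)
    a, b = segment.start, segment.end
    while b - a > 2:
        cur = _trend_fraction(sgn[a:b], trend)
        f_first = _trend_fraction(sgn[a + 1:b], trend)
        f_last = _trend_fraction(sgn[a:b - 1], trend)
        best = max(f_first, f_last)
        if best <= cur:
            break
        if f_first >= f_last:
            a += 1
        else:
            b -= 1
    if b - a < 2 or t[b - 1] - t[a] < min_duration:
        return None
    return segment.with_bounds(a, b)


def characterize_segment(
    segment: FlightSegment,
    series: FixSeries,
    wind: Optional[WindVector] = None,
) -> FlightSegment:
    """Fill the per-segment characterization fields in place.

    Duration and altitudinal change span first to last fix; travel distance
    sums step lengths; mean vertical speed is altitudinal change over
    duration; mean angular speed is the mean absolute heading change per
    second.  Wind support and side-wind are filled for glides only, from
    per-fix wind annotation columns or the supplied uniform ``wind``.
    """
    df = series.df
    a, b = segment.start, segment.end
    if b - a < 2:
        raise ValueError("degenerate segment: need at least 2 fixes")
    t = df["time"].to_numpy()[a:b]
    x = df["x"].to_numpy()[a:b]
    y = df["y"].to_numpy()[a:b]
    alt = df["altitude_agl"].to_numpy()[a:b]

    segment.start_time = float(t[0])
    segment.duration = float(t[-1] - t[0])
    segment.altitudinal_change = float(alt[-1] - alt[0])
    segment.travel_distance = float(np.hypot(np.diff(x), np.diff(y)).sum())
    segment.mean_vertical_speed = segment.altitudinal_change / segment.duration
    segment.mean_horizontal_speed = segment.travel_distance / segment.duration
    segment.start_lon = float(df["lon"].to_numpy()[a])
    segment.start_lat = float(df["lat"].to_numpy()[a])

    dt = np.diff(t)
    heads = df["heading"].to_numpy()[a + 1:b]
    if len(heads) >= 2:
        dh = np.diff(heads)
        dh = (dh + 180.0) % 360.0 - 180.0
        segment.mean_angular_speed = float(np.mean(np.abs(dh) / dt[1:]))

    uw = vw = None
    if wind is not None:
        uw = np.full(b - a, wind.u)
        vw = np.full(b - a, wind.v)
    elif "wind_u" in df.columns:
        uw = df["wind_u"].to_numpy()[a:b]
        vw = df["wind_v"].to_numpy()[a:b]
    if uw is not None and np.all(np.isfinite(uw)):
        hr = np.radians(df["heading"].to_numpy()[a:b])
        gs = df["ground_speed"].to_numpy()[a:b]
        gx, gy = gs * np.sin(hr), gs * np.cos(hr)
        segment.mean_airspeed = float(np.mean(np.hypot(gx - uw, gy - vw)))
        if segment.mode == MODE_GLIDE:
            ex, ey = np.sin(hr), np.cos(hr)
            segment.wind_support = float(np.mean(uw * ex + vw * ey))
            # positive = wind from the bird's left
            segment.side_wind = float(np.mean(uw * ey - vw * ex))
    return segment


def segment_track(series: FixSeries, config: Optional[SegConfig] = None) -> list[FlightSegment]:
    """Run both stages and characterize everything; segments sorted by start."""
    cfg = config or SegConfig()
    thermals = detect_thermals(series, config=cfg)
    trends = detect_trend_segments(series, thermals, config=cfg)
    segs = sorted(thermals + trends, key=lambda s: s.start)
    for s in segs:
        characterize_segment(s, series)
    return segs
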