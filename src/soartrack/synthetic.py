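"""Synthetic soaring-track generator with known ground truth.

Emulates the structure of high-frequency vulture foraging tracks: days of
flight alternating circling thermal climbs (a helix of configured radius and
period whose centre drifts with the wind), straight inter-thermal glides,
occasional straight linear-soaring climbs, roost fixes at 600-s cadence
around the flight, tri-axial accelerometer bursts every minute in flight
(flapping bursts carry a sinusoid on the heave axis), and gridded wind/TKE
fields.  Gaussian GPS noise is added last, so every geometric quantity has an
exact pre-noise truth value recorded alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .config import SimulationConfig
from .core import AccBurst, FixSeries, WindField, IntegrityError
from .geo import aeqd_inverse

EPOCH_BASE = 1_372_636_800.0  # 2013-07-01T00:00:00Z; any fixed base works

TRUTH_MODES = ("ground", "thermal", "glide", "linear", "flap")
DETECTED_MODES = ("thermal", "glide", "linear", "undetected")


@dataclass
class SyntheticTrack:
    """A simulated track plus its exact ground truth."""

    series: FixSeries
    bursts: list[AccBurst]
    truth_labels: np.ndarray  # per-fix mode label, aligned with series.df
    truth_segments: pd.DataFrame  # one row per true thermal/glide/linear phase
    clean_xyz: np.ndarray  # (n, 3) pre-noise x, y, altitude
    config: SimulationConfig


def _wind_profile_fn(config: SimulationConfig):
    prof = np.asarray(config.wind_profile, dtype=float)
    prof = prof[np.argsort(prof[:, 0])]
    alts, us, vs = prof[:, 0], prof[:, 1], prof[:, 2]

    def wind_at(alt):
        alt = np.asarray(alt, dtype=float)
        return np.interp(alt, alts, us), np.interp(alt, alts, vs)

    return wind_at


def _trunc_normal(rng, mean, sd, lo):
    """One draw, redrawn (up to 20x) then clipped to stay above ``lo``."""
    for _ in range(20):
        v = rng.normal(mean, sd)
        if v >= lo:
            return v
    return lo


def simulate_track(config: SimulationConfig) -> SyntheticTrack:
    """Generate a 1-Hz flight track for one bird over ``config.n_days`` days.

    Same config (including seed) gives bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    wind_at = _wind_profile_fn(config)

    times: list[np.ndarray] = []
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    alts: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    seg_rows: list[dict] = []
    burst_meta: list[tuple[float, bool]] = []  # (time, flapping)
    n_emitted = 0

    def emit(t, x, y, alt, label):
        nonlocal n_emitted
        t = np.atleast_1d(np.asarray(t, dtype=float))
        times.append(t)
        xs.append(np.atleast_1d(np.asarray(x, dtype=float)))
        ys.append(np.atleast_1d(np.asarray(y, dtype=float)))
        alts.append(np.atleast_1d(np.asarray(alt, dtype=float)))
        labels.append(np.full(len(t), label, dtype=object))
        n_emitted += len(t)

    for day in range(config.n_days):
        t0 = EPOCH_BASE + day * 86400.0 + config.day_start_s
        # --- morning roost fixes, 600-s cadence, ground speed << 2 m/s
        for k in range(3):
            emit(t0 + 600.0 * k, rng.normal(0, 3.0), rng.normal(0, 3.0), 0.0, "ground")

        t = t0 + 1800.0
        x, y = float(xs[-1][-1]), float(ys[-1][-1])
        alt = config.start_altitude
        heading = rng.uniform(0.0, 360.0)
        flight_start = t
        emit(t, x, y, alt, "thermal")  # first airborne fix, owned by phase 1

        # phase plan: thermal/glide pairs with linear legs spliced in
        linear_after = set(
            rng.choice(config.thermals_per_day, size=min(config.linear_per_day,
                                                         config.thermals_per_day),
                       replace=False)
        ) if config.linear_per_day > 0 else set()

        for k in range(config.thermals_per_day):
            # ---- thermal-soaring phase: drifting helix
            dur = int(round(_trunc_normal(rng, *config.thermal_duration, 60.0)))
            updraft = _trunc_normal(rng, *config.thermal_updraft, config.thermal_sink + 0.2)
            base_climb = updraft - config.thermal_sink
            s = 1.0 if rng.random() < 0.5 else -1.0  # +1 = clockwise
            omega = 360.0 / config.circle_period
            R = config.thermal_radius

            h0 = heading
            rad0 = np.array([-np.cos(np.radians(h0)), np.sin(np.radians(h0))]) * s
            cx, cy = x - R * rad0[0], y - R * rad0[1]

            t_rel = np.arange(1, dur + 1, dtype=float)
            h = h0 + s * omega * t_rel
            hr = np.radians(h)
            radial = np.stack([-np.cos(hr), np.sin(hr)], axis=1) * s

            wu0, wv0 = wind_at(alt)
            wspd0 = float(np.hypot(wu0, wv0))
            if config.lee_updraft_boost != 0.0 and wspd0 > 1e-9:
                wdir = np.array([wu0, wv0]) / wspd0
                downwind = (radial @ wdir) > 0
                climb_t = base_climb + config.lee_updraft_boost * downwind
            else:
                climb_t = np.full(dur, base_climb)
            alt_t = alt + np.cumsum(climb_t)
            keep = alt_t <= 2500.0
            if not np.all(keep):
                dur = max(int(np.argmin(keep)), 1)
                t_rel, h, radial, climb_t, alt_t = (
                    t_rel[:dur], h[:dur], radial[:dur], climb_t[:dur], alt_t[:dur])

            wu_t, wv_t = wind_at(alt_t)
            cx_t = cx + np.cumsum(wu_t)
            cy_t = cy + np.cumsum(wv_t)
            px = cx_t + R * radial[:, 0]
            py = cy_t + R * radial[:, 1]

            i0 = n_emitted - 1  # entry fix belongs to previous phase; span starts at first new fix
            emit(t + t_rel, px, py, alt_t, "thermal")
            mean_alt = float(np.mean(alt_t))
            wu_m, wv_m = wind_at(mean_alt)
            seg_rows.append(dict(
                day=day, kind="thermal", start=i0 + 1, end=n_emitted,
                t_start=t + 1, t_end=t + dur,
                duration=float(dur - 1),
                climb_rate=float((alt_t[-1] - alt_t[0]) / (dur - 1)) if dur > 1 else base_climb,
                base_climb=base_climb, updraft=updraft,
                radius=R, period=config.circle_period,
                direction="CW" if s > 0 else "CCW",
                wind_u=float(wu_m), wind_v=float(wv_m),
            ))
            t += dur
            x, y, alt = float(px[-1]), float(py[-1]), float(alt_t[-1])
            heading = float(np.mod(h[-1], 360.0))
            thermal_dur = dur

            # ---- glide (plus optional linear-soaring leg spliced after it)
            phases = [("glide", None)]
            if k in linear_after:
                phases.append(("linear", None))
            for kind, _ in phases:
                if kind == "glide":
                    if config.efficiency_target is not None:
                        dur_g = max(int(round(config.efficiency_target * thermal_dur
                                              / config.glide_airspeed)), 10)
                    else:
                        dur_g = int(round(_trunc_normal(rng, *config.glide_duration, 30.0)))
                    vz = -config.glide_sink
                else:
                    dur_g = int(round(_trunc_normal(rng, *config.linear_duration, 20.0)))
                    vz = config.linear_climb
                hr0 = np.radians(heading)
                vair = config.glide_airspeed * np.array([np.sin(hr0), np.cos(hr0)])
                t_rel = np.arange(1, dur_g + 1, dtype=float)
                alt_t = alt + vz * t_rel
                if vz < 0:
                    keep = alt_t >= 80.0
                    if not np.all(keep):
                        dur_g = max(int(np.argmin(keep)), 1)
                        t_rel, alt_t = t_rel[:dur_g], alt_t[:dur_g]
                wu_t, wv_t = wind_at(alt_t)
                px = x + vair[0] * t_rel + np.cumsum(wu_t)
                py = y + vair[1] * t_rel + np.cumsum(wv_t)
                i0 = n_emitted
                emit(t + t_rel, px, py, alt_t, kind)
                dist = float(np.hypot(np.diff(np.r_[x, px]), np.diff(np.r_[y, py])).sum())
                wu_m, wv_m = wind_at(float(np.mean(alt_t)))
                seg_rows.append(dict(
                    day=day, kind=kind, start=i0, end=n_emitted,
                    t_start=t + 1, t_end=t + dur_g,
                    duration=float(dur_g - 1),
                    climb_rate=vz, base_climb=vz, updraft=np.nan,
                    radius=np.nan, period=np.nan, direction="",
                    wind_u=float(wu_m), wind_v=float(wv_m),
                    travel_distance=dist, preceding_thermal_duration=float(thermal_dur),
                ))
                t += dur_g
                x, y, alt = float(px[-1]), float(py[-1]), float(alt_t[-1])

        flight_end = t
        # --- ACC bursts every burst_interval_s of flight
        tb = flight_start
        while tb + 3.8 <= flight_end:
            burst_meta.append((tb, bool(rng.random() < config.flapping_prob_per_burst)))
            tb += config.burst_interval_s
        # --- evening roost fixes
        for k in range(1, 3):
            emit(t + 600.0 * k, x + rng.normal(0, 3.0), y + rng.normal(0, 3.0), 0.0, "ground")

    time_arr = np.concatenate(times)
    x_arr = np.concatenate(xs)
    y_arr = np.concatenate(ys)
    alt_arr = np.concatenate(alts)
    label_arr = np.concatenate(labels)
    clean_xyz = np.stack([x_arr, y_arr, alt_arr], axis=1)

    # flapping bursts relabel the covered seconds
    flap_times = [tb for tb, f in burst_meta if f]
    if flap_times:
        order = np.searchsorted(time_arr, np.asarray(flap_times))
        for tb, idx in zip(flap_times, order):
            j = idx
            while j < len(time_arr) and time_arr[j] < tb + 3.8:
                if label_arr[j] != "ground":
                    label_arr[j] = "flap"
                j += 1

    # GPS noise added last: Gaussian with sd gps_noise_sd per component,
    # autocorrelated in time (AR(1), correlation time gps_noise_corr_s) the
    # way real GPS error is — consecutive-fix position differences are far
    # less noisy than the absolute positions.
    if config.gps_noise_sd > 0:
        noise = _gps_noise(rng, time_arr, config.gps_noise_sd, config.gps_noise_corr_s)
        x_n, y_n, alt_n = x_arr + noise[:, 0], y_arr + noise[:, 1], alt_arr + noise[:, 2]
    else:
        x_n, y_n, alt_n = x_arr, y_arr, alt_arr
    lon, lat = aeqd_inverse(x_n, y_n, *config.origin)

    df = pd.DataFrame({
        "bird_id": "SYN1", "time": time_arr, "lon": lon, "lat": lat,
        "altitude_agl": alt_n,
    })
    series = FixSeries.from_fixes(df, origin=config.origin)

    bursts = [
        _make_burst(rng, config, tb, flapping)
        for tb, flapping in burst_meta
    ]

    seg_df = pd.DataFrame(seg_rows)
    return SyntheticTrack(
        series=series, bursts=bursts, truth_labels=label_arr,
        truth_segments=seg_df, clean_xyz=clean_xyz, config=config,
    )


def _gps_noise(rng, t: np.ndarray, sd: float, corr_s: float) -> np.ndarray:
    """Stationary AR(1) Gaussian error, marginal sd ``sd`` per component."""
    n = len(t)
    white = rng.normal(0.0, sd, size=(n, 3))
    if corr_s <= 0 or n < 2:
        return white
    rho = np.exp(-np.diff(t) / corr_s)
    out = np.empty_like(white)
    out[0] = white[0]
    for i in range(1, n):
        r = rho[i - 1]
        out[i] = r * out[i - 1] + np.sqrt(1.0 - r * r) * white[i]
    return out


def _make_burst(rng, config: SimulationConfig, tb: float, flapping: bool) -> AccBurst:
    n = AccBurst.N_SAMPLES
    tau = np.arange(n) / AccBurst.SAMPLE_HZ
    samples = rng.normal(0.0, config.acc_noise_sd, size=(3, n))
    samples[2] += 1.0  # gravity on heave
    if flapping:
        samples[2] += config.acc_flap_amplitude * np.sin(
            2.0 * np.pi * config.acc_flap_freq * tau
        )
    return AccBurst(bird_id="SYN1", time=tb, samples=samples, truth_flap=flapping)


# ---------------------------------------------------------------------------
# wind / TKE grid


def simulate_wind_field(
    config: SimulationConfig,
    extent: Sequence[Sequence[float]],
    x_step: float = 1000.0,
    t_step: float = 300.0,
) -> WindField:
    """Grid the configured wind profile and TKE over a space-time extent.

    ``extent`` = ((x0, x1), (y0, y1), (z0, z1), (t0, t1)) in local metres /
    seconds.  U and V follow ``wind_profile`` linearly in altitude and are
    constant in x, y, t; TKE is ``tke_background`` plus any configured
    Gaussian bumps.  Default spacing 1 km horizontal, 5 min temporal.
    """
    (x0, x1), (y0, y1), (z0, z1), (t0, t1) = extent
    if not (x1 > x0 and y1 > y0 and z1 > z0 and t1 > t0):
        raise ValueError("extent must be non-degenerate in every axis")

    def _axis(a, b, step):
        lo = np.floor(a / step) * step
        hi = np.ceil(b / step) * step
        if hi <= lo:
            hi = lo + step
        return np.arange(lo, hi + step / 2, step)

    xax = _axis(x0, x1, x_step)
    yax = _axis(y0, y1, x_step)
    tax = _axis(t0, t1, t_step)
    prof_alts = sorted({float(r[0]) for r in config.wind_profile})
    zax = np.array(sorted({*prof_alts, float(max(z0 - 50.0, 0.0)), float(z1 + 50.0)}))
    zax = zax[(zax >= min(z0, prof_alts[0]) - 51.0)]

    wind_at = _wind_profile_fn(config)
    uz, vz = wind_at(zax)
    shape = (len(xax), len(yax), len(zax), len(tax))
    U = np.broadcast_to(uz[None, None, :, None], shape).copy()
    V = np.broadcast_to(vz[None, None, :, None], shape).copy()

    tke_xy = np.full((len(xax), len(yax)), config.tke_background, dtype=float)
    for bx, by, br, amp in config.tke_bumps:
        gx = np.exp(-((xax - bx) ** 2)[:, None] / (2 * br**2))
        gy = np.exp(-((yax - by) ** 2)[None, :] / (2 * br**2))
        tke_xy += amp * gx * gy
    TKE = np.broadcast_to(tke_xy[:, :, None, None], shape).copy()

    ds = xr.Dataset(
        {
            "U": (("x", "y", "z", "t"), U),
            "V": (("x", "y", "z", "t"), V),
            "TKE": (("x", "y", "z", "t"), TKE),
        },
        coords={"x": xax, "y": yax, "z": zax, "t": tax},
        attrs={
            "origin_lon": config.origin[0], "origin_lat": config.origin[1],
            "units_x": "m", "units_z": "m", "units_t": "s",
            "units_U": "m/s", "units_TKE": "J/kg",
        },
    )
    return WindField(ds)


def extent_for_series(series: FixSeries, pad_m: float = 2500.0,
                      pad_t: float = 600.0) -> tuple:
    """Bounding extent of a series, padded, for :func:`simulate_wind_field`."""
    df = series.df
    return (
        (df["x"].min() - pad_m, df["x"].max() + pad_m),
        (df["y"].min() - pad_m, df["y"].max() + pad_m),
        (0.0, max(float(df["altitude_agl"].max()), 100.0) + 200.0),
        (df["time"].min() - pad_t, df["time"].max() + pad_t),
    )


# ---------------------------------------------------------------------------
# truth scoring


def truth_confusion(track: SyntheticTrack, detected: Sequence) -> pd.DataFrame:
    """Seconds-level confusion table: rows true modes, columns detected modes.

    ``detected`` are FlightSegments indexing ``track.series``; they must be
    pairwise disjoint.  Every fix contributes one second to exactly one cell,
    so row sums equal the true per-mode seconds.
    """
    n = len(track.series)
    det = np.full(n, "undetected", dtype=object)
    claimed = np.zeros(n, dtype=bool)
    for seg in detected:
        if seg.start < 0 or seg.end > n:
            raise IntegrityError("detected segment outside track span")
        if claimed[seg.start:seg.end].any():
            raise IntegrityError("detected segments overlap")
        claimed[seg.start:seg.end] = True
        det[seg.start:seg.end] = seg.mode

    table = pd.DataFrame(0, index=list(TRUTH_MODES), columns=list(DETECTED_MODES))
    truth = track.truth_labels
    for tm in TRUTH_MODES:
        mask = truth == tm
        if not mask.any():
            continue
        vals, counts = np.unique(det[mask], return_counts=True)
        for v, c in zip(vals, counts):
            table.loc[tm, v] = int(c)
    return table
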