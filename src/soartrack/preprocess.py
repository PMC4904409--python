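"""Flight detection, vertical-speed smoothing, ODBA and flapping classification.

The vertical-speed smoother is the robust-lowess construction: local linear
regression over a centred 5-s window with tricube distance weights, iterated
twice with bisquare reweighting of residuals, so single-fix altitude spikes
are down-weighted rather than smeared.  Windows truncate at the edges of a
contiguous 1-Hz stretch and never bridge gaps longer than ``max_gap_s``.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np

from .config import AccConfig, SmoothConfig
from .core import AccBurst, FixSeries

log = logging.getLogger(__name__)


def detect_flight(series: FixSeries, threshold: float = 2.0) -> np.ndarray:
    """In-flight mask: ground speed above ``threshold`` m/s.

    Isolated single-fix state flips (1-s GPS blips) are removed with a 3-fix
    majority filter.  The mask is stored on ``series.df['in_flight']`` and
    returned.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 fixes to derive ground speed")
    speed = series.df["ground_speed"].to_numpy()
    mask = speed > threshold
    if len(mask) >= 3:
        trip = mask[:-2].astype(int) + mask[1:-1] + mask[2:]
        mask = mask.copy()
        mask[1:-1] = trip >= 2
    series.df["in_flight"] = mask
    return mask


def contiguous_stretches(series: FixSeries, max_gap_s: float = 2.0,
                         in_flight_only: bool = False) -> list[tuple[int, int]]:
    """Half-open index ranges of temporally contiguous (and optionally
    in-flight) runs; a time gap > ``max_gap_s`` always splits."""
    t = series.df["time"].to_numpy()
    n = len(t)
    if n == 0:
        return []
    ok = np.ones(n, dtype=bool)
    if in_flight_only:
        ok = series.df["in_flight"].to_numpy().astype(bool)
    breaks = np.zeros(n, dtype=bool)
    breaks[0] = True
    if n > 1:
        breaks[1:] = np.diff(t) > max_gap_s
    out = []
    start = None
    for i in range(n):
        if not ok[i]:
            if start is not None:
                out.append((start, i))
                start = None
        elif start is None:
            start = i
        elif breaks[i]:
            out.append((start, i))
            start = i
    if start is not None:
        out.append((start, n))
    return out


def _robust_local_linear(t: np.ndarray, y: np.ndarray, half: float,
                         iters: int) -> np.ndarray:
    """Vectorized tricube-weighted local linear fit at every point."""
    n = len(t)
    if n == 1:
        return y.copy()
    k = int(np.ceil(half))  # index reach; window membership re-checked on time
    offs = np.arange(-k, k + 1)
    idx = np.clip(np.arange(n)[:, None] + offs[None, :], 0, n - 1)
    tt = t[idx]
    dt = tt - t[:, None]
    in_win = (np.abs(dt) <= half + 1e-9) & (np.arange(n)[:, None] + offs[None, :] >= 0) \
        & (np.arange(n)[:, None] + offs[None, :] <= n - 1)
    yy = y[idx]

    d = np.abs(dt)
    dmax = np.where(in_win, d, -np.inf).max(axis=1)
    dmax = np.where(dmax > 0, dmax, 1.0)
    u = np.clip(d / dmax[:, None], 0.0, 1.0)
    w_dist = np.where(in_win, (1.0 - u**3) ** 3, 0.0)

    w_rob = np.ones(n)
    fitted = y.copy()
    for it in range(iters + 1):
        w = w_dist * w_rob[idx]
        s0 = w.sum(axis=1)
        s1 = (w * dt).sum(axis=1)
        s2 = (w * dt * dt).sum(axis=1)
        sy = (w * yy).sum(axis=1)
        sxy = (w * dt * yy).sum(axis=1)
        den = s0 * s2 - s1 * s1
        with np.errstate(invalid="ignore", divide="ignore"):
            slope = np.where(np.abs(den) > 1e-12, (s0 * sxy - s1 * sy) / np.where(den != 0, den, 1.0), 0.0)
            fitted = np.where(s0 > 0, (sy - slope * s1) / np.where(s0 > 0, s0, 1.0), y)
        if it == iters:
            break
        resid = y - fitted
        s = np.median(np.abs(resid))
        if s < 1e-12:
            # mostly-perfect fit: fall back to the mean absolute residual so
            # isolated spikes are still down-weighted
            s = np.mean(np.abs(resid))
        if s < 1e-12:
            break
        w_rob = np.clip(1.0 - (resid / (6.0 * s)) ** 2, 0.0, 1.0) ** 2
    return fitted


def smooth_vertical_speed(
    series: FixSeries,
    window: float = 5.0,
    config: Optional[SmoothConfig] = None,
) -> np.ndarray:
    """Robust locally-weighted smoothing of the raw vertical-speed series.

    Raw vertical speed is the first difference of altitude over elapsed time
    (already derived on the series); the smoothed value at each fix is the
    robust local linear fit over the centred ``window``-second span of its
    contiguous stretch.  Stored on ``series.df['vspeed_smooth']``.
    """
    cfg = config or SmoothConfig(window_s=window)
    t = series.df["time"].to_numpy(dtype=float)
    v = series.df["vspeed_raw"].to_numpy(dtype=float)
    out = v.copy()
    for i0, i1 in contiguous_stretches(series, max_gap_s=cfg.max_gap_s):
        if i1 - i0 >= 2:
            v_st = v[i0:i1].copy()
            if i0 > 0:
                # the first fix of a post-gap stretch carries a cross-gap
                # difference; never let it leak into the stretch
                v_st[0] = v_st[1]
            out[i0:i1] = _robust_local_linear(
                t[i0:i1], v_st, cfg.window_s / 2.0, cfg.robust_iters
            )
    series.df["vspeed_smooth"] = out
    return out


def compute_odba(burst: AccBurst, static_window: float = 3.8) -> float:
    """Overall Dynamic Body Acceleration of one burst, in g.

    Per axis the static component is the running mean over ``static_window``
    seconds (the whole burst by default — bursts are short and disjoint, so
    there is no within-burst drift to track); ODBA is the per-sample sum of
    absolute dynamic components, averaged over the burst.
    """
    if not np.all(np.isfinite(burst.samples)):
        raise ValueError("burst contains missing/non-finite samples")
    k = int(round(static_window * AccBurst.SAMPLE_HZ))
    if k >= burst.N_SAMPLES:
        static = burst.samples.mean(axis=1, keepdims=True)
    else:
        from scipy.ndimage import uniform_filter1d

        static = uniform_filter1d(burst.samples, size=k, axis=1, mode="nearest")
    dyn = burst.samples - static
    odba = float(np.abs(dyn).sum(axis=0).mean())
    burst.odba = odba
    return odba


def classify_flapping(burst: AccBurst, config: Optional[AccConfig] = None) -> str:
    """Rule-based flapping/passive classification of one burst.

    Flapping iff ODBA exceeds the configured threshold AND the fraction of
    heave-axis spectral power (DC removed) inside the configured band is at
    least ``power_fraction``.  This transparent two-feature rule stands in
    for a field-trained supervised classifier; thresholds are frozen in
    :class:`~soartrack.config.AccConfig`.
    """
    cfg = config or AccConfig()
    if burst.odba is None:
        compute_odba(burst)
    heave = burst.samples[2] - burst.samples[2].mean()
    power = np.abs(np.fft.rfft(heave)) ** 2
    freqs = np.fft.rfftfreq(burst.N_SAMPLES, d=1.0 / AccBurst.SAMPLE_HZ)
    total = power[1:].sum()
    lo, hi = cfg.band_hz
    band = power[(freqs >= lo) & (freqs <= hi)].sum()
    frac = band / total if total > 0 else 0.0
    label = "flapping" if (burst.odba > cfg.odba_threshold_g and frac >= cfg.power_fraction) else "passive"
    burst.flap_label = label
    return label


def classify_bursts(bursts: Sequence[AccBurst], config: Optional[AccConfig] = None) -> int:
    """Classify every valid burst; returns the number rejected (logged)."""
    rejected = 0
    for b in bursts:
        try:
            classify_flapping(b, config)
        except ValueError:
            rejected += 1
    if rejected:
        log.warning("rejected %d malformed ACC bursts", rejected)
    return rejected
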