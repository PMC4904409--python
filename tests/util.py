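"""Shared test helpers: hand-built tracks with exact geometry."""

import numpy as np
import pandas as pd

from soartrack.core import FixSeries
from soartrack.geo import aeqd_inverse

ORIGIN = (35.0, 31.0)


def series_from_xy(t, x, y, alt, bird_id="T1", origin=ORIGIN, in_flight=True):
    """FixSeries from planar coordinates (metres) via the local projection."""
    lon, lat = aeqd_inverse(np.asarray(x, float), np.asarray(y, float), *origin)
    df = pd.DataFrame({
        "bird_id": bird_id, "time": np.asarray(t, float),
        "lon": lon, "lat": lat, "altitude_agl": np.asarray(alt, float),
    })
    s = FixSeries.from_fixes(df, origin=origin)
    if in_flight:
        s.df["in_flight"] = True
    return s


def series_from_vspeed(vspeed, dt=1.0):
    """FixSeries whose smoothed vertical speed is exactly ``vspeed``.

    Positions move at 10 m/s east so every fix is in flight; the
    vspeed_smooth column is set directly (trend-rule tests control the sign
    sequence exactly).
    """
    v = np.asarray(vspeed, float)
    n = len(v)
    t = np.arange(n) * dt
    alt = 500 + np.r_[0.0, np.cumsum(v[1:]) * dt]
    s = series_from_xy(t, 10.0 * t, np.zeros(n), alt)
    s.df["vspeed_smooth"] = v
    return s


def helix_track(radius=30.0, period=20.0, duration=120, climb=1.4,
                drift=(0.0, 0.0), direction=1, noise_sd=0.0, seed=0,
                start_alt=300.0):
    """Clean circling track: helix of given radius/period, advected by a
    uniform drift, climbing at ``climb`` m/s.  direction=+1 is clockwise."""
    rng = np.random.default_rng(seed)
    t = np.arange(duration, dtype=float)
    ang = np.radians(direction * 360.0 / period * t)
    x = radius * np.sin(ang) + drift[0] * t
    y = radius * np.cos(ang) + drift[1] * t
    alt = start_alt + climb * t
    if noise_sd > 0:
        x = x + rng.normal(0, noise_sd, duration)
        y = y + rng.normal(0, noise_sd, duration)
        alt = alt + rng.normal(0, noise_sd, duration)
    return series_from_xy(t, x, y, alt)
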