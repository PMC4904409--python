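"""Wind annotation and wind-relative flight geometry.

Fixes are annotated by multilinear interpolation of the gridded U/V/TKE
field; airspeed is ground velocity minus wind; circling events get a wind
context (shear magnitude and class, circling direction, per-fix angle to the
wind and lee/windward side of the drifting thermal column).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np

from .config import WindConfig
from .core import FixSeries, FlightSegment, WindField, WindVector
from .geo import aeqd_forward

log = logging.getLogger(__name__)


class CalmWindError(ValueError):
    """Wind-relative geometry is undefined in calm air."""


class IndeterminateTurnError(ValueError):
    """Net turn too small to assign a circling direction."""


def _grid_arrays(fld: WindField):
    axes = [fld.axis(d) for d in fld.DIMS]
    # pad singleton axes so linear interpolation stays defined
    arrs = {v: fld.ds[v].to_numpy() for v in fld.REQUIRED_VARS}
    for k, ax in enumerate(axes):
        if len(ax) == 1:
            axes[k] = np.array([ax[0] - 0.5, ax[0] + 0.5])
            for v in arrs:
                arrs[v] = np.repeat(arrs[v], 2, axis=k)
    return axes, arrs


def _multilinear(axes, arr, pts):
    """Multilinear interpolation of ``arr`` at clipped query points.

    ``pts`` has shape (n, 4).  Plain product-of-weights over the 2^4 corner
    nodes, in float64 — agrees with nested 1-D linear interpolation to a few
    ulp, which the oracle tests rely on.
    """
    n = pts.shape[0]
    idx = []
    frac = []
    for k, ax in enumerate(axes):
        j = np.clip(np.searchsorted(ax, pts[:, k], side="right") - 1, 0, len(ax) - 2)
        w = (pts[:, k] - ax[j]) / (ax[j + 1] - ax[j])
        idx.append(j)
        frac.append(np.clip(w, 0.0, 1.0))
    out = np.zeros(n)
    for corner in range(16):
        w = np.ones(n)
        ix = []
        for k in range(4):
            hi = (corner >> k) & 1
            w = w * (frac[k] if hi else (1.0 - frac[k]))
            ix.append(idx[k] + hi)
        out += w * arr[tuple(ix)]
    return out


def interpolate_wind(fld: WindField, lon, lat, altitude_agl, time) -> WindVector:
    """Wind vector at one query point (multilinear in x, y, z, t).

    Spatial queries outside the grid hull clamp to the edge (logged); time
    outside the grid span is an error — wind is never extrapolated in time.
    """
    u, v, tke = _interp_arrays(
        fld, np.atleast_1d(lon), np.atleast_1d(lat),
        np.atleast_1d(altitude_agl), np.atleast_1d(time),
    )
    return WindVector(u=float(u[0]), v=float(v[0]), tke_1km=float(tke[0]))


def _interp_arrays(fld: WindField, lon, lat, alt, time):
    axes, arrs = _grid_arrays(fld)
    x, y = aeqd_forward(lon, lat, *fld.origin)
    t = np.asarray(time, dtype=float)
    if np.any(t < axes[3][0] - 1e-9) or np.any(t > axes[3][-1] + 1e-9):
        raise ValueError("query time outside wind-grid span (no extrapolation)")

    pts = np.stack([np.atleast_1d(x), np.atleast_1d(y),
                    np.atleast_1d(np.asarray(alt, dtype=float)),
                    np.atleast_1d(t)], axis=-1).astype(float)
    clipped = pts.copy()
    for k in range(4):
        clipped[:, k] = np.clip(pts[:, k], axes[k][0], axes[k][-1])
    n_clamped = int(np.sum(np.any(np.abs(clipped[:, :3] - pts[:, :3]) > 1e-9, axis=-1)))
    if n_clamped:
        log.info("clamped %d wind queries to the grid edge", n_clamped)

    u = _multilinear(axes, arrs["U"], clipped)
    v = _multilinear(axes, arrs["V"], clipped)
    # TKE at 1-km scale: mean over the corners of the enclosing horizontal cell
    xax, yax = axes[0], axes[1]
    ix = np.clip(np.searchsorted(xax, clipped[:, 0], side="right") - 1, 0, len(xax) - 2)
    iy = np.clip(np.searchsorted(yax, clipped[:, 1], side="right") - 1, 0, len(yax) - 2)
    tke = np.zeros_like(u)
    for dx in (0, 1):
        for dy in (0, 1):
            corner = clipped.copy()
            corner[:, 0] = xax[ix + dx]
            corner[:, 1] = yax[iy + dy]
            tke += _multilinear(axes, arrs["TKE"], corner)
    return u, v, tke / 4.0


def annotate_series(series: FixSeries, fld: WindField) -> FixSeries:
    """Add per-fix ``wind_u``, ``wind_v``, ``tke_1km`` columns (vectorized)."""
    df = series.df
    u, v, tke = _interp_arrays(
        fld, df["lon"].to_numpy(), df["lat"].to_numpy(),
        df["altitude_agl"].to_numpy(), df["time"].to_numpy(),
    )
    df["wind_u"], df["wind_v"], df["tke_1km"] = u, v, tke
    return series


def decompose_wind(ground_velocity, wind: WindVector):
    """Split the wind about the travel direction.

    Returns ``(airspeed_vector, airspeed, wind_support, side_wind)`` with
    wind support along the ground-track direction and side-wind positive
    when the wind comes from the bird's left.
    """
    g = np.asarray(ground_velocity, dtype=float)
    gs = float(np.hypot(g[0], g[1]))
    if gs <= 0:
        raise ValueError("zero ground velocity: travel direction undefined")
    e = g / gs
    right = np.array([e[1], -e[0]])  # 90 deg clockwise of travel
    w = np.array([wind.u, wind.v])
    air = g - w
    return air, float(np.hypot(*air)), float(w @ e), float(w @ right)


def relative_flight_angle(heading: float, wind: WindVector) -> float:
    """Circular heading-vs-wind angle in (-180, 180]; 0 = headwind.

    Positive when the wind origin lies to the bird's left, so clockwise and
    counter-clockwise circling stay distinguishable.
    """
    if wind.speed <= 1e-9:
        raise CalmWindError("relative flight angle undefined in calm wind")
    d = (heading - wind.direction_from + 180.0) % 360.0 - 180.0
    return 180.0 if d == -180.0 else float(d)


def circling_direction(thermal: FlightSegment, series: FixSeries) -> str:
    """\"CW\" or \"CCW\" from the summed signed heading change of the event."""
    heads = series.df["heading"].to_numpy()[thermal.start + 1:thermal.end]
    if len(heads) < 3:
        raise IndeterminateTurnError("too few steps to assess turning")
    dh = np.diff(heads)
    dh = (dh + 180.0) % 360.0 - 180.0
    net = float(dh.sum())
    if abs(net) < 180.0:
        raise IndeterminateTurnError(f"net turn {net:.0f} deg < 180 deg")
    return "CW" if net > 0 else "CCW"


def lee_windward_partition(
    thermal: FlightSegment,
    series: FixSeries,
    wind: WindVector,
    center: Optional[np.ndarray] = None,
):
    """Per-fix lee/windward labels within a drifting thermal column.

    Each fix is projected onto the wind axis through the drift-compensated
    circle centre: the downwind half of the column is the lee side.  Returns
    ``(labels, lee_mean_climb, windward_mean_climb)`` using smoothed vertical
    speeds; withheld (ValueError) in calm wind or without a usable centre.
    """
    if wind.speed <= 1e-9:
        raise CalmWindError("lee/windward partition undefined in calm wind")
    if center is None:
        from .metrics import thermal_center_trajectory

        center = thermal_center_trajectory(thermal, series, wind)
    df = series.df
    a, b = thermal.start, thermal.end
    pos = np.stack([df["x"].to_numpy()[a:b], df["y"].to_numpy()[a:b]], axis=1)
    wdir = np.array([wind.u, wind.v]) / wind.speed
    proj = (pos - center) @ wdir
    labels = np.where(proj > 0, "lee", "windward")
    vs = df["vspeed_smooth"].to_numpy()[a:b]
    lee = vs[labels == "lee"]
    windward = vs[labels == "windward"]
    lee_mean = float(np.mean(lee)) if len(lee) else np.nan
    ww_mean = float(np.mean(windward)) if len(windward) else np.nan
    return labels, lee_mean, ww_mean


@dataclass
class ThermalWindContext:
    """Wind context of one thermal-soaring event."""

    wind_shear: float  # horizontal wind speed at thermal altitude, m/s
    shear_class: str  # "low" | "mid" | "high"
    circling_direction: str = ""
    relative_angles: np.ndarray = dc_field(default_factory=lambda: np.array([]))
    sides: np.ndarray = dc_field(default_factory=lambda: np.array([]))
    lee_mean_climb: float = np.nan
    windward_mean_climb: float = np.nan


def wind_shear_class(
    thermal: FlightSegment,
    series: FixSeries,
    fld: Optional[WindField] = None,
    config: Optional[WindConfig] = None,
) -> ThermalWindContext:
    """Wind shear (mean horizontal wind speed along the thermal) and class.

    Classes split at the configured cut-points: [0, 2) low, [2, 6] mid,
    (6, inf) high by default.  Uses per-fix annotation columns, or
    interpolates from ``fld`` when the series is not yet annotated.
    """
    cfg = config or WindConfig()
    df = series.df
    a, b = thermal.start, thermal.end
    if "wind_u" in df.columns and np.all(np.isfinite(df["wind_u"].to_numpy()[a:b])):
        u = df["wind_u"].to_numpy()[a:b]
        v = df["wind_v"].to_numpy()[a:b]
    elif fld is not None:
        u, v, _ = _interp_arrays(
            fld, df["lon"].to_numpy()[a:b], df["lat"].to_numpy()[a:b],
            df["altitude_agl"].to_numpy()[a:b], df["time"].to_numpy()[a:b],
        )
    else:
        raise ValueError("series not annotated and no wind field given")
    shear = float(np.mean(np.hypot(u, v)))
    lo, hi = cfg.shear_cutpoints
    cls = "low" if shear < lo else ("mid" if shear <= hi else "high")
    return ThermalWindContext(wind_shear=shear, shear_class=cls)


def thermal_wind_context(
    thermal: FlightSegment,
    series: FixSeries,
    fld: Optional[WindField] = None,
    config: Optional[WindConfig] = None,
) -> ThermalWindContext:
    """Full wind context: shear class, circling direction, per-fix angle to
    the wind and lee/windward partition (withheld parts stay empty/NaN)."""
    ctx = wind_shear_class(thermal, series, fld, config)
    df = series.df
    a, b = thermal.start, thermal.end
    u = df["wind_u"].to_numpy()[a:b]
    v = df["wind_v"].to_numpy()[a:b]
    mean_wind = WindVector(u=float(np.mean(u)), v=float(np.mean(v)))
    try:
        ctx.circling_direction = circling_direction(thermal, series)
    except IndeterminateTurnError:
        pass
    if mean_wind.speed > 1e-9:
        heads = df["heading"].to_numpy()[a:b]
        ctx.relative_angles = np.array(
            [relative_flight_angle(h, mean_wind) for h in heads]
        )
        try:
            ctx.sides, ctx.lee_mean_climb, ctx.windward_mean_climb = (
                lee_windward_partition(thermal, series, mean_wind)
            )
        except ValueError:
            pass
    return ctx
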