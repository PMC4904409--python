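"""Local azimuthal-equidistant projection on a spherical Earth.

Tracks are analysed in a local planar frame (metres east/north of a fixed
reference origin).  At foraging-trip scales (tens of km) the spherical
azimuthal-equidistant projection is exact enough that ground-truth geometry
survives a forward/inverse round trip to sub-millimetre accuracy.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_M = 6_371_000.0


def aeqd_forward(lon, lat, origin_lon, origin_lat):
    """Project WGS84 degrees to local (x east, y north) metres.

    Parameters are scalars or arrays (broadcast).  Returns ``(x, y)``.
    """
    lam = np.radians(np.asarray(lon, dtype=float))
    phi = np.radians(np.asarray(lat, dtype=float))
    lam0 = np.radians(origin_lon)
    phi0 = np.radians(origin_lat)

    cos_c = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam - lam0)
    cos_c = np.clip(cos_c, -1.0, 1.0)
    c = np.arccos(cos_c)
    # k -> 1 as c -> 0 (point at the origin)
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(c > 1e-12, c / np.sin(np.where(c > 1e-12, c, 1.0)), 1.0)
    x = EARTH_RADIUS_M * k * np.cos(phi) * np.sin(lam - lam0)
    y = EARTH_RADIUS_M * k * (
        np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam - lam0)
    )
    return x, y


def aeqd_inverse(x, y, origin_lon, origin_lat):
    """Inverse of :func:`aeqd_forward`; returns ``(lon, lat)`` in degrees."""
    x = np.asarray(x, dtype=float) / EARTH_RADIUS_M
    y = np.asarray(y, dtype=float) / EARTH_RADIUS_M
    lam0 = np.radians(origin_lon)
    phi0 = np.radians(origin_lat)

    c = np.hypot(x, y)
    safe_c = np.where(c > 1e-12, c, 1.0)
    sin_c, cos_c = np.sin(c), np.cos(c)
    phi = np.arcsin(
        np.where(
            c > 1e-12,
            cos_c * np.sin(phi0) + y * sin_c * np.cos(phi0) / safe_c,
            np.sin(phi0),
        )
    )
    lam = lam0 + np.arctan2(
        x * sin_c,
        safe_c * np.cos(phi0) * cos_c - y * sin_c * np.sin(phi0),
    )
    lam = np.where(c > 1e-12, lam, lam0)
    return np.degrees(lam), np.degrees(phi)
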