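"""Core in-memory containers shared across the package.

A :class:`FixSeries` is the canonical per-bird GPS container: a pandas
DataFrame of 3-D fixes with derived kinematics (local planar coordinates,
ground speed, heading, raw vertical speed) plus the projection origin.
Accelerometer bursts, flight segments and wind fields get small dataclasses;
the wind grid itself is an :class:`xarray.Dataset`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
import xarray as xr

from .geo import aeqd_forward

#: per-fix columns every FixSeries carries after construction
FIX_COLUMNS = [
    "bird_id", "time", "lon", "lat", "altitude_agl",
    "x", "y", "ground_speed", "heading", "vspeed_raw",
]

MODE_THERMAL = "thermal"
MODE_GLIDE = "glide"
MODE_LINEAR = "linear"


class SchemaError(ValueError):
    """A file or frame does not match the declared schema."""


class IntegrityError(ValueError):
    """Data violates a structural invariant (ordering, ranges)."""


def _wrap_heading(deg):
    return np.mod(deg, 360.0)


@dataclass
class FixSeries:
    """Ordered GPS fixes of one bird with derived kinematics.

    ``df`` rows are strictly time-ordered; ``origin`` is the lon/lat of the
    local azimuthal-equidistant frame in which ``x``/``y`` are metres.
    """

    df: pd.DataFrame
    origin: tuple[float, float]

    def __post_init__(self):
        t = self.df["time"].to_numpy()
        if len(t) and np.any(np.diff(t) <= 0):
            raise IntegrityError("timestamps must be strictly increasing within a bird")
        if np.any(np.abs(self.df["lat"].to_numpy()) > 90.0):
            raise IntegrityError("latitude outside [-90, 90]")
        if not np.all(np.isfinite(self.df["altitude_agl"].to_numpy())):
            raise IntegrityError("non-finite altitude")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def bird_id(self) -> str:
        return str(self.df["bird_id"].iloc[0]) if len(self.df) else ""

    @classmethod
    def from_fixes(
        cls,
        df: pd.DataFrame,
        origin: Optional[tuple[float, float]] = None,
    ) -> "FixSeries":
        """Build a series from raw fixes (bird_id, time, lon, lat, altitude_agl).

        Sorts by time, projects to the local frame and derives ground speed,
        heading and raw vertical speed from consecutive fixes (rates use the
        actual elapsed time, so dropped fixes do not corrupt speeds).
        """
        required = {"bird_id", "time", "lon", "lat", "altitude_agl"}
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(f"missing mandatory column(s): {sorted(missing)}")
        if df["bird_id"].nunique() > 1:
            raise IntegrityError("FixSeries holds exactly one bird")
        df = df.sort_values("time").reset_index(drop=True)
        if origin is None:
            origin = (float(df["lon"].iloc[0]), float(df["lat"].iloc[0]))
        x, y = aeqd_forward(df["lon"].to_numpy(), df["lat"].to_numpy(), *origin)
        df = df.assign(x=x, y=y)

        t = df["time"].to_numpy(dtype=float)
        alt = df["altitude_agl"].to_numpy(dtype=float)
        n = len(df)
        speed = np.zeros(n)
        heading = np.zeros(n)
        vraw = np.zeros(n)
        if n >= 2:
            dt = np.diff(t)
            dx = np.diff(x)
            dy = np.diff(y)
            step_speed = np.hypot(dx, dy) / dt
            step_heading = _wrap_heading(np.degrees(np.arctan2(dx, dy)))
            step_vraw = np.diff(alt) / dt
            speed[1:] = step_speed
            heading[1:] = step_heading
            vraw[1:] = step_vraw
            # first fix inherits the first step so masks/means stay length-n
            speed[0], heading[0], vraw[0] = step_speed[0], step_heading[0], step_vraw[0]
        df = df.assign(ground_speed=speed, heading=heading, vspeed_raw=vraw)
        return cls(df=df, origin=origin)

    def day_key(self) -> pd.Series:
        """UTC date string per fix, the per-bird-day grouping key."""
        return pd.to_datetime(self.df["time"], unit="s", utc=True).dt.strftime("%Y-%m-%d")


@dataclass
class AccBurst:
    """One tri-axial accelerometer burst: 3 axes x 38 samples at 10 Hz (g).

    Axis order is (surge, sway, heave); heave carries gravity and the
    flapping signal.  ``odba`` and ``flap_label`` are filled by preprocess.
    """

    bird_id: str
    time: float
    samples: np.ndarray  # shape (3, 38)
    odba: Optional[float] = None
    flap_label: Optional[str] = None  # "flapping" | "passive"
    truth_flap: Optional[bool] = None  # generator ground truth, if synthetic

    SAMPLE_HZ = 10.0
    N_SAMPLES = 38

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.shape != (3, self.N_SAMPLES):
            raise SchemaError(
                f"burst must be 3 axes x {self.N_SAMPLES} samples, got {self.samples.shape}"
            )

    @property
    def duration_s(self) -> float:
        return self.N_SAMPLES / self.SAMPLE_HZ


@dataclass
class FlightSegment:
    """A contiguous track slice with a flight-mode label and its characterization.

    ``start``/``end`` index the owning FixSeries half-open; times/duration use
    elapsed seconds between the first and last fix of the slice.
    """

    mode: str
    start: int
    end: int  # exclusive
    bird_id: str = ""
    start_time: float = np.nan
    duration: float = np.nan
    altitudinal_change: float = np.nan
    travel_distance: float = np.nan
    mean_vertical_speed: float = np.nan
    mean_horizontal_speed: float = np.nan
    mean_angular_speed: float = np.nan
    start_lon: float = np.nan
    start_lat: float = np.nan
    wind_support: float = np.nan  # glides only
    side_wind: float = np.nan  # glides only
    mean_airspeed: float = np.nan
    radius_m: float = np.nan  # thermals only
    circling_dir: str = ""  # "CW" | "CCW" | ""
    wind_shear: float = np.nan
    shear_class: str = ""
    tke_1km: float = np.nan

    def __post_init__(self):
        if self.end <= self.start:
            raise IntegrityError("segment must contain at least one step")

    @property
    def n_fixes(self) -> int:
        return self.end - self.start

    def with_bounds(self, start: int, end: int) -> "FlightSegment":
        return replace(self, start=start, end=end)


@dataclass
class WindVector:
    """Interpolated local wind with optional 1-km TKE context."""

    u: float
    v: float
    tke_1km: float = np.nan

    @property
    def speed(self) -> float:
        return float(np.hypot(self.u, self.v))

    @property
    def direction_toward(self) -> float:
        """Degrees clockwise from north the wind blows TOWARD."""
        return float(_wrap_heading(np.degrees(np.arctan2(self.u, self.v))))

    @property
    def direction_from(self) -> float:
        return float(_wrap_heading(self.direction_toward + 180.0))


@dataclass
class WindField:
    """Gridded U/V wind and TKE on monotone x/y/z/t axes.

    Backed by an :class:`xarray.Dataset` with data variables ``U``, ``V``,
    ``TKE`` (m/s, m/s, J/kg) over dims ``x``/``y`` (m in the local frame),
    ``z`` (m above ground) and ``t`` (s).  The projection origin is stored in
    attrs so lon/lat queries resolve into the grid frame.
    """

    ds: xr.Dataset

    REQUIRED_VARS = ("U", "V", "TKE")
    DIMS = ("x", "y", "z", "t")

    def __post_init__(self):
        for v in self.REQUIRED_VARS:
            if v not in self.ds:
                raise SchemaError(f"wind grid is missing variable {v!r}")
            if tuple(self.ds[v].dims) != self.DIMS:
                raise SchemaError(f"variable {v!r} must have dims {self.DIMS}")
        for d in self.DIMS:
            ax = self.ds[d].to_numpy()
            if len(ax) == 0:
                raise SchemaError(f"axis {d!r} is empty")
            if len(ax) > 1 and np.any(np.diff(ax) <= 0):
                raise IntegrityError(f"axis {d!r} must be strictly increasing")

    @property
    def origin(self) -> tuple[float, float]:
        return (float(self.ds.attrs["origin_lon"]), float(self.ds.attrs["origin_lat"]))

    def axis(self, name: str) -> np.ndarray:
        return self.ds[name].to_numpy().astype(float)
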