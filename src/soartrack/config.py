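"""Configuration objects.

Every threshold the analysis uses lives here with its field default; values
that published soaring studies state (2 m/s in-flight threshold, 5-s
smoothing window, 45-s minimum thermal duration, 90% trend fraction, 200-km /
0.7 foraging-day cut-offs, 2 and 6 m/s wind-shear cut-points) keep those
values as defaults.  The simulation defaults are calibrated once to the
summary statistics of the griffon-vulture study system this package targets
(thermal climb 1.4 m/s, thermal duration 150 s, glide sink 0.75 m/s, glide
duration 192 s, circling radius ~36 m, adult flapping proportion 0.02) and
are not tuning knobs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import yaml


def _positive(name, value):
    if not np.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be finite and > 0, got {value!r}")


@dataclass
class SimulationConfig:
    """Ground-truth parameters of the synthetic soaring-track generator."""

    seed: int = 0
    n_days: int = 20
    thermals_per_day: int = 20
    thermal_updraft: tuple[float, float] = (1.5, 0.3)  # m/s (mean, sd)
    thermal_sink: float = 0.1  # m/s sink relative to air while circling
    thermal_radius: float = 35.9  # m
    circle_period: float = 20.0  # s per full circle
    thermal_duration: tuple[float, float] = (150.0, 30.0)  # s (mean, sd)
    glide_airspeed: float = 9.0  # m/s
    glide_sink: float = 0.75  # m/s, positive down
    glide_duration: tuple[float, float] = (192.0, 40.0)  # s (mean, sd)
    efficiency_target: Optional[float] = None  # m glide per s climb; couples glide to climb
    linear_per_day: int = 1
    linear_duration: tuple[float, float] = (80.0, 10.0)  # s
    linear_climb: float = 1.8  # m/s
    wind_profile: tuple[tuple[float, float, float], ...] = (
        (0.0, 1.0, 0.0),
        (1000.0, 2.5, 0.0),
        (3000.0, 4.0, 0.0),
    )  # (altitude m, u m/s, v m/s)
    tke_background: float = 0.8  # J/kg
    tke_bumps: tuple[tuple[float, float, float, float], ...] = ()  # (x, y, radius_m, amplitude)
    flapping_prob_per_burst: float = 0.02
    lee_updraft_boost: float = 0.0  # m/s added on the downwind half of the column
    gps_noise_sd: float = 3.0  # m, per horizontal component and vertical
    gps_noise_corr_s: float = 60.0  # AR(1) correlation time of the GPS error; 0 = white
    acc_flap_freq: float = 4.0  # Hz
    acc_flap_amplitude: float = 1.0  # g
    acc_noise_sd: float = 0.05  # g, white noise on every axis
    start_altitude: float = 300.0  # m AGL at first thermal entry
    origin: tuple[float, float] = (35.0, 31.0)  # lon, lat of local frame / roost
    day_start_s: float = 6 * 3600.0  # seconds after midnight UTC, flight starts later
    burst_interval_s: float = 60.0

    def validate(self) -> "SimulationConfig":
        for name in (
            "thermal_radius", "circle_period", "glide_airspeed", "glide_sink",
            "linear_climb", "acc_flap_freq", "acc_flap_amplitude", "burst_interval_s",
        ):
            _positive(name, getattr(self, name))
        for name in ("thermal_updraft", "thermal_duration", "glide_duration", "linear_duration"):
            mean, sd = getattr(self, name)
            _positive(name + ".mean", mean)
            if not np.isfinite(sd) or sd < 0:
                raise ValueError(f"{name}.sd must be finite and >= 0")
        if not (0.0 <= self.flapping_prob_per_burst <= 1.0):
            raise ValueError("flapping_prob_per_burst must be in [0, 1]")
        if not np.isfinite(self.gps_noise_sd) or self.gps_noise_sd < 0:
            raise ValueError("gps_noise_sd must be finite and >= 0")
        if self.n_days < 1 or self.thermals_per_day < 1:
            raise ValueError("n_days and thermals_per_day must be >= 1")
        for row in self.wind_profile:
            if len(row) != 3 or not all(np.isfinite(v) for v in row):
                raise ValueError("wind_profile rows must be finite (altitude, u, v)")
        return self


@dataclass
class FlightConfig:
    speed_threshold_ms: float = 2.0


@dataclass
class SmoothConfig:
    window_s: float = 5.0
    robust_iters: int = 2
    max_gap_s: float = 2.0


@dataclass
class AccConfig:
    odba_threshold_g: float = 0.3
    band_hz: tuple[float, float] = (3.0, 5.0)
    power_fraction: float = 0.25


@dataclass
class SegConfig:
    min_thermal_s: float = 45.0
    lookback_s: float = 120.0
    trend_fraction: float = 0.9
    min_trend_s: float = 10.0
    merge_gap_s: float = 10.0


@dataclass
class WindConfig:
    shear_cutpoints: tuple[float, float] = (2.0, 6.0)
    side_sign_convention: str = "left_positive"


@dataclass
class PolarConfig:
    """Quadratic glide polar sink(v) = a v^2 + b v + c, sink positive down."""

    a: float = 0.0115
    b: float = 0.0
    c: float = 0.93
    v_range: tuple[float, float] = (6.0, 30.0)


@dataclass
class FilterConfig:
    max_travel_km: float = 200.0
    max_straightness: float = 0.7
    roost_km: float = 60.0


@dataclass
class MetricsConfig:
    pair_max_gap_s: float = 10.0
    rafi_definition: str = "normalized"  # or "ratio"


@dataclass
class StatsConfig:
    shear_bin_width: float = 1.0
    unit_of_analysis: str = "individual"  # or "thermal"


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; nested per-stage blocks."""

    seed: int = 0
    out_dir: str = "soartrack_out"
    log_level: str = "INFO"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    flight: FlightConfig = field(default_factory=FlightConfig)
    smooth: SmoothConfig = field(default_factory=SmoothConfig)
    acc: AccConfig = field(default_factory=AccConfig)
    seg: SegConfig = field(default_factory=SegConfig)
    wind: WindConfig = field(default_factory=WindConfig)
    polar: PolarConfig = field(default_factory=PolarConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = dict(d)
        for key, sub in (
            ("simulation", SimulationConfig), ("flight", FlightConfig),
            ("smooth", SmoothConfig), ("acc", AccConfig), ("seg", SegConfig),
            ("wind", WindConfig), ("polar", PolarConfig), ("filter", FilterConfig),
            ("metrics", MetricsConfig), ("stats", StatsConfig),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                block = {
                    k: tuple(tuple(r) if isinstance(r, list) else r for r in v)
                    if isinstance(v, list) else v
                    for k, v in kwargs[key].items()
                }
                kwargs[key] = sub(**block)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
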