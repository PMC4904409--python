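"""Per-thermal, per-glide and per-day flight-performance metrics.

Climb rate and drift-compensated circling radius per thermal, glide-polar
reference speeds and the risk-aversion index (RAFI) per glide,
soaring-gliding efficiency per thermal-glide pair, and daily path metrics
with the foraging-trip filter.
"""

import numpy as np

from soartrack import (GlidePolar, SimulationConfig, WindVector,
                       best_glide_speed, circling_radius, climb_rate,
                       daily_summary, foraging_day_filter, maccready_speed,
                       rafi, simulate_track, thermal_glide_pairs)
from soartrack import detect_flight, smooth_vertical_speed, segment_track
from soartrack.preprocess import classify_bursts, compute_odba

cfg = SimulationConfig(seed=2, n_days=2,
                       wind_profile=((0.0, 2.0, 0.0), (3000.0, 2.0, 0.0)))
track = simulate_track(cfg)
from soartrack import annotate_series, simulate_wind_field
from soartrack.synthetic import extent_for_series

annotate_series(track.series, simulate_wind_field(cfg, extent_for_series(track.series)))
detect_flight(track.series)
smooth_vertical_speed(track.series)
for b in track.bursts:
    compute_odba(b)
classify_bursts(track.bursts)
segments = segment_track(track.series)

thermals = [s for s in segments if s.mode == "thermal"]
wind = WindVector(2.0, 0.0)
climbs = [climb_rate(s, track.series) for s in thermals]
radii = []
for s in thermals:
    try:
        radii.append(circling_radius(s, track.series, wind))
    except ValueError:
        pass
print(f"{len(thermals)} thermals: climb {np.mean(climbs):.2f} m/s, "
      f"radius {np.mean(radii):.1f} m (generator: 1.40 m/s, 35.9 m)")

# airspeed choice relative to a quadratic glide polar sink(v) = a v^2 + c
polar = GlidePolar(a=0.0115, b=0.0, c=0.93)
v_bg = best_glide_speed(polar)
v_mc = maccready_speed(polar, climb_expected=1.4)
print(f"best-glide speed {v_bg:.1f} m/s, MacCready speed for 1.4 m/s climbs {v_mc:.1f} m/s")

pairs = thermal_glide_pairs(segments, track.series)
print(f"{len(pairs)} thermal-glide pairs, efficiency "
      f"{pairs['efficiency'].mean():.1f} m of glide per s of climb")

days = daily_summary(track.series, segments, track.bursts)
for d in days:
    foraging_day_filter(d)
    print(f"{d.date}: travel {d.travel_distance_km:.0f} km, straightness "
          f"{d.straightness:.2f}, flapping {d.flapping_proportion:.1%}, "
          f"ODBA {d.mean_odba:.2f} g, foraging day: {d.is_foraging_day}")
# A RAFI of 1 means gliding at best-glide speed (risk-averse); 0 means at
# the MacCready optimum for the preceding climb (risk-prone).
example_rafi = rafi(next(s for s in segments if s.mode == "glide" and np.isfinite(s.mean_airspeed)),
                    preceding_climb=1.4, polar=polar)
print(f"RAFI of the first annotated glide: {example_rafi:.2f}")
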