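"""Wind annotation and wind-relative flight geometry.

Builds a gridded wind field (1-km / 5-min resolution, linear-in-altitude
profile), interpolates it onto a circling track, and computes airspeed,
wind support/side-wind, circling direction and the lee/windward split of a
drifting thermal.
"""

import numpy as np

from soartrack import (SimulationConfig, WindVector, simulate_track,
                       simulate_wind_field, annotate_series, decompose_wind,
                       relative_flight_angle, circling_direction,
                       lee_windward_partition, wind_shear_class)
from soartrack import detect_flight, smooth_vertical_speed, segment_track
from soartrack.synthetic import extent_for_series

cfg = SimulationConfig(seed=4, n_days=1, thermals_per_day=6,
                       lee_updraft_boost=0.4,
                       wind_profile=((0.0, 3.0, 0.0), (3000.0, 3.0, 0.0)))
track = simulate_track(cfg)
field = simulate_wind_field(cfg, extent_for_series(track.series))
annotate_series(track.series, field)   # adds wind_u / wind_v / tke_1km per fix
print(f"wind grid: {dict(field.ds.sizes)}")

# vector algebra at one fix: ground velocity vs the 3 m/s westerly
air, airspeed, support, side = decompose_wind((10.0, 0.0), WindVector(3.0, 0.0))
print(f"flying east at 10 m/s in a 3 m/s westerly: airspeed {airspeed:.1f} m/s, "
      f"wind support {support:+.1f}, side wind {side:+.1f}")
print(f"heading north in that wind: angle to wind {relative_flight_angle(0.0, WindVector(3.0, 0.0)):+.0f} deg"
      " (0 = headwind, +/-180 = tailwind)")

detect_flight(track.series)
smooth_vertical_speed(track.series)
thermals = [s for s in segment_track(track.series) if s.mode == "thermal"]
wind = WindVector(3.0, 0.0)
t0 = thermals[0]
ctx = wind_shear_class(t0, track.series)
_, lee, windward = lee_windward_partition(t0, track.series, wind)
print(f"\nfirst thermal: shear {ctx.wind_shear:.1f} m/s ({ctx.shear_class}), "
      f"circling {circling_direction(t0, track.series)}")
print(f"lee-side mean climb {lee:.2f} m/s vs windward {windward:.2f} m/s")
# The generator boosts updraft on the downwind half, and the positional
# lee/windward rule recovers that asymmetry.
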