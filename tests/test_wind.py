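"""Wind interpolation, decomposition and wind-relative circling geometry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from soartrack.config import SimulationConfig
from soartrack.core import FlightSegment, WindField, WindVector, MODE_THERMAL
from soartrack.geo import aeqd_forward, aeqd_inverse
from soartrack.preprocess import detect_flight, smooth_vertical_speed
from soartrack.segmentation import segment_track
from soartrack.synthetic import simulate_track, simulate_wind_field
from soartrack.wind import (CalmWindError, IndeterminateTurnError,
                            annotate_series, circling_direction,
                            decompose_wind, interpolate_wind,
                            lee_windward_partition, relative_flight_angle,
                            wind_shear_class)

from util import ORIGIN, helix_track

import xarray as xr


def _random_field(rng, nx=3, ny=4, nz=3, nt=3):
    axes = {
        "x": np.sort(rng.uniform(-5e3, 5e3, nx)),
        "y": np.sort(rng.uniform(-5e3, 5e3, ny)),
        "z": np.sort(rng.uniform(0, 2e3, nz)),
        "t": np.sort(rng.uniform(0, 3600, nt)),
    }
    shape = (nx, ny, nz, nt)
    ds = xr.Dataset(
        {v: (("x", "y", "z", "t"), rng.normal(size=shape)) for v in ("U", "V", "TKE")},
        coords=axes,
        attrs={"origin_lon": ORIGIN[0], "origin_lat": ORIGIN[1]},
    )
    return WindField(ds)


def _nested_interp_oracle(fld, x, y, z, t, var):
    """Brute-force nested 1-D linear interpolation, axis by axis."""
    arr = fld.ds[var].to_numpy()
    for axis_name, q in (("x", x), ("y", y), ("z", z), ("t", t)):
        ax = fld.axis(axis_name)
        q = np.clip(q, ax[0], ax[-1])
        j = int(np.clip(np.searchsorted(ax, q) - 1, 0, len(ax) - 2))
        w = (q - ax[j]) / (ax[j + 1] - ax[j])
        arr = (1 - w) * arr[j] + w * arr[j + 1]
    return float(arr)


def test_interpolation_matches_nested_1d_oracle():
    rng = np.random.default_rng(0)
    for rep in range(5):
        fld = _random_field(rng)
        for _ in range(20):
            x = rng.uniform(fld.axis("x")[0], fld.axis("x")[-1])
            y = rng.uniform(fld.axis("y")[0], fld.axis("y")[-1])
            z = rng.uniform(fld.axis("z")[0], fld.axis("z")[-1])
            t = rng.uniform(fld.axis("t")[0], fld.axis("t")[-1])
            lon, lat = aeqd_inverse(x, y, *ORIGIN)
            wv = interpolate_wind(fld, lon, lat, z, t)
            # oracle evaluated at the projected planar point, so this isolates
            # the interpolation step from the lon/lat round trip
            xp, yp = aeqd_forward(lon, lat, *ORIGIN)
            assert wv.u == pytest.approx(_nested_interp_oracle(fld, xp, yp, z, t, "U"), abs=1e-12)
            assert wv.v == pytest.approx(_nested_interp_oracle(fld, xp, yp, z, t, "V"), abs=1e-12)


def test_uniform_field_interpolates_to_itself():
    fld = simulate_wind_field(SimulationConfig(wind_profile=((0.0, 3.0, 0.0),)),
                              ((-2e3, 2e3), (-2e3, 2e3), (0, 1000), (0, 900)))
    wv = interpolate_wind(fld, ORIGIN[0] + 0.003, ORIGIN[1] - 0.002, 430.0, 555.0)
    assert wv.u == pytest.approx(3.0, abs=1e-9)
    assert wv.v == pytest.approx(0.0, abs=1e-9)


def test_midpoint_between_z_levels():
    cfg = SimulationConfig(wind_profile=((0.0, 0.0, 0.0), (1000.0, 4.0, 0.0)))
    fld = simulate_wind_field(cfg, ((-2e3, 2e3), (-2e3, 2e3), (0, 1000), (0, 900)))
    assert interpolate_wind(fld, *ORIGIN, 500.0, 300.0).u == pytest.approx(2.0, abs=1e-12)


def test_time_outside_span_is_an_error():
    fld = simulate_wind_field(SimulationConfig(), ((-2e3, 2e3), (-2e3, 2e3), (0, 1000), (0, 900)))
    with pytest.raises(ValueError):
        interpolate_wind(fld, *ORIGIN, 400.0, 99_999.0)


# --- decomposition --------------------------------------------------------


def test_collinear_wind_decomposition():
    air, speed, support, side = decompose_wind((10.0, 0.0), WindVector(2.0, 0.0))
    assert speed == pytest.approx(8.0)
    assert support == pytest.approx(2.0)
    assert side == pytest.approx(0.0)


def test_crosswind_decomposition():
    air, speed, support, side = decompose_wind((10.0, 0.0), WindVector(0.0, 3.0))
    assert support == pytest.approx(0.0)
    assert abs(side) == pytest.approx(3.0)
    assert speed == pytest.approx(np.sqrt(109.0))


def test_no_wind_identity():
    air, speed, support, side = decompose_wind((4.0, 3.0), WindVector(0.0, 0.0))
    assert speed == pytest.approx(5.0)
    assert support == 0.0 and side == 0.0


def test_zero_ground_velocity_rejected():
    with pytest.raises(ValueError):
        decompose_wind((0.0, 0.0), WindVector(1.0, 0.0))


@settings(deadline=None, derandomize=True, max_examples=100)
@given(st.tuples(*[st.floats(-30, 30) for _ in range(4)]))
def test_decomposition_conserves_and_is_orthogonal(vals):
    gx, gy, wu, wv = vals
    if np.hypot(gx, gy) < 1e-6:
        return
    wind = WindVector(wu, wv)
    air, speed, support, side = decompose_wind((gx, gy), wind)
    np.testing.assert_allclose(air + [wu, wv], [gx, gy], atol=1e-9)
    assert support**2 + side**2 == pytest.approx(wind.speed**2, abs=1e-7)


def test_side_wind_sign_convention_left_positive():
    # heading north, wind vector (3, 0) blows toward the east, i.e. comes
    # FROM the west — the bird's left — so the convention makes it positive
    _, _, _, side = decompose_wind((0.0, 10.0), WindVector(3.0, 0.0))
    assert side == pytest.approx(3.0)


# --- relative flight angle ------------------------------------------------


def test_headwind_is_zero():
    # flying north into wind coming from the north
    assert relative_flight_angle(0.0, WindVector(0.0, -5.0)) == pytest.approx(0.0)


def test_tailwind_is_180():
    assert abs(relative_flight_angle(0.0, WindVector(0.0, 5.0))) == pytest.approx(180.0)


def test_crosswind_angle_matches_circular_oracle():
    # flying east, wind from the north
    ang = relative_flight_angle(90.0, WindVector(0.0, -5.0))
    wind_from = 0.0
    oracle = (90.0 - wind_from + 180.0) % 360.0 - 180.0
    assert ang == pytest.approx(oracle)
    assert abs(ang) == pytest.approx(90.0)


def test_angle_circularly_continuous():
    w = WindVector(1.0, 1.0)
    a = relative_flight_angle(359.9, w)
    b = relative_flight_angle(0.1, w)
    assert abs((a - b + 180.0) % 360.0 - 180.0) < 0.3


def test_calm_wind_flagged():
    with pytest.raises(CalmWindError):
        relative_flight_angle(10.0, WindVector(0.0, 0.0))


# --- circling direction ---------------------------------------------------


def test_generator_cw_helix_detected_cw():
    s = helix_track(direction=1, duration=60)
    seg = FlightSegment(mode=MODE_THERMAL, start=0, end=60)
    assert circling_direction(seg, s) == "CW"


def test_mirrored_track_flips_direction():
    s = helix_track(direction=1, duration=60)
    from util import series_from_xy
    mirrored = series_from_xy(s.df["time"], -s.df["x"].to_numpy(),
                              s.df["y"].to_numpy(), s.df["altitude_agl"])
    seg = FlightSegment(mode=MODE_THERMAL, start=0, end=60)
    assert circling_direction(seg, mirrored) == "CCW"


def test_net_turn_matches_angle_summation_oracle():
    s = helix_track(direction=-1, duration=90, period=30.0)
    seg = FlightSegment(mode=MODE_THERMAL, start=0, end=90)
    heads = s.df["heading"].to_numpy()[1:90]
    net = np.sum((np.diff(heads) + 180.0) % 360.0 - 180.0)
    assert circling_direction(seg, s) == ("CW" if net > 0 else "CCW") == "CCW"


def test_small_net_turn_indeterminate():
    t = np.arange(30.0)
    from util import series_from_xy
    s = series_from_xy(t, 9.0 * t, np.zeros(30), 500 + t)
    with pytest.raises(IndeterminateTurnError):
        circling_direction(FlightSegment(mode=MODE_THERMAL, start=0, end=30), s)


# --- lee / windward -------------------------------------------------------


def test_partition_withheld_in_calm_wind():
    s = helix_track(duration=80)
    s.df["vspeed_smooth"] = 1.0
    seg = FlightSegment(mode=MODE_THERMAL, start=0, end=80)
    with pytest.raises(CalmWindError):
        lee_windward_partition(seg, s, WindVector(0.0, 0.0))


def test_fix_downwind_of_centre_is_lee():
    # thermal drifting with the 4 m/s westerly it sits in
    s = helix_track(duration=80, drift=(4.0, 0.0))
    s.df["vspeed_smooth"] = 1.0
    seg = FlightSegment(mode=MODE_THERMAL, start=0, end=80)
    labels, _, _ = lee_windward_partition(seg, s, WindVector(4.0, 0.0))
    t = s.df["time"].to_numpy()[:80]
    rel_x = s.df["x"].to_numpy()[:80] - 4.0 * t  # position about the moving core
    assert (labels[rel_x > 5.0] == "lee").all()
    assert (labels[rel_x < -5.0] == "windward").all()


def test_lee_enhanced_updraft_recovered():
    """Generator boost on the downwind half shows up as lee > windward."""
    cfg = SimulationConfig(seed=5, n_days=1, thermals_per_day=6,
                           lee_updraft_boost=0.5,
                           wind_profile=((0.0, 3.0, 0.0), (3000.0, 3.0, 0.0)))
    tr = simulate_track(cfg)
    s = tr.series
    detect_flight(s)
    smooth_vertical_speed(s)
    wind = WindVector(3.0, 0.0)
    diffs = []
    for seg in segment_track(s):
        if seg.mode == MODE_THERMAL:
            _, lee, windward = lee_windward_partition(seg, s, wind)
            diffs.append(lee - windward)
    assert len(diffs) >= 4
    assert np.mean(diffs) > 0.1


# --- wind shear class -----------------------------------------------------


@pytest.mark.parametrize("speed,expected", [(1.0, "low"), (4.0, "mid"), (7.0, "high")])
def test_shear_class_cutpoints(speed, expected):
    s = helix_track(duration=60)
    s.df["wind_u"] = speed
    s.df["wind_v"] = 0.0
    seg = FlightSegment(mode=MODE_THERMAL, start=0, end=60)
    ctx = wind_shear_class(seg, s)
    assert ctx.wind_shear == pytest.approx(speed)
    assert ctx.shear_class == expected


def test_annotation_columns_added(small_sim):
    series = small_sim.series
    cfg = small_sim.config
    fld = simulate_wind_field(cfg, (
        (series.df["x"].min() - 2e3, series.df["x"].max() + 2e3),
        (series.df["y"].min() - 2e3, series.df["y"].max() + 2e3),
        (0.0, float(series.df["altitude_agl"].max()) + 200.0),
        (series.df["time"].min() - 600, series.df["time"].max() + 600),
    ))
    annotate_series(series, fld)
    assert np.isfinite(series.df["wind_u"]).all()
    assert np.isfinite(series.df["tke_1km"]).all()
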