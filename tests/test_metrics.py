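"""Climb rate, circling radius, glide-polar speeds, RAFI, efficiency, daily
path metrics and the foraging-trip filter."""

import numpy as np
import pytest

from soartrack.config import SimulationConfig
from soartrack.core import FlightSegment, WindVector, MODE_GLIDE, MODE_THERMAL
from soartrack.metrics import (DailySummary, GlidePolar, best_glide_speed,
                               circling_radius, climb_rate, daily_summary,
                               foraging_day_filter, maccready_speed, rafi,
                               soaring_gliding_efficiency,
                               thermal_glide_pairs, thermal_selection_tke)
from soartrack.segmentation import characterize_segment
from util import helix_track, series_from_xy


def test_climb_rate_arithmetic():
    s = helix_track(radius=30.0, period=20.0, duration=151, climb=1.4)
    seg = FlightSegment(mode=MODE_THERMAL, start=0, end=151)
    assert climb_rate(seg, s) == pytest.approx(1.4, rel=1e-9)


def test_non_climbing_segment_rejected():
    s = helix_track(duration=60, climb=-0.2)
    seg = FlightSegment(mode=MODE_THERMAL, start=0, end=60)
    with pytest.raises(ValueError):
        climb_rate(seg, s)


# --- circling radius ------------------------------------------------------


def test_radius_exact_after_drift_compensation():
    """Uniform drift must cancel exactly: 30-m helix -> 30.000000 m."""
    s = helix_track(radius=30.0, period=20.0, duration=120, climb=1.0,
                    drift=(4.0, 1.0))
    seg = FlightSegment(mode=MODE_THERMAL, start=0, end=120)
    r = circling_radius(seg, s, WindVector(4.0, 1.0))
    assert r == pytest.approx(30.0, abs=1e-6)


def test_radius_with_gps_noise_within_a_metre():
    rng_radii = []
    for seed in range(10):
        s = helix_track(radius=30.0, period=20.0, duration=120, climb=1.0,
                        drift=(4.0, 0.0), noise_sd=3.0, seed=seed)
        seg = FlightSegment(mode=MODE_THERMAL, start=0, end=120)
        rng_radii.append(circling_radius(seg, s, WindVector(4.0, 0.0)))
    assert abs(np.mean(rng_radii) - 30.0) < 1.0


def test_radius_kinematic_cross_check():
    """r = v_h / omega on a clean helix agrees with the circle fit to 5%."""
    period, radius = 24.0, 42.0
    s = helix_track(radius=radius, period=period, duration=120, climb=1.0)
    seg = FlightSegment(mode=MODE_THERMAL, start=0, end=120)
    characterize_segment(seg, s)
    omega = np.radians(seg.mean_angular_speed)
    r_kin = seg.mean_horizontal_speed / omega
    r_fit = circling_radius(seg, s, WindVector(0.0, 0.0))
    assert r_fit == pytest.approx(radius, rel=0.01)
    assert r_kin == pytest.approx(r_fit, rel=0.05)


def test_radius_needs_a_full_loop():
    s = helix_track(radius=30.0, period=60.0, duration=30, climb=1.0)
    seg = FlightSegment(mode=MODE_THERMAL, start=0, end=30)
    with pytest.raises(ValueError):
        circling_radius(seg, s, WindVector(0.0, 0.0))


# --- polar speeds ---------------------------------------------------------


def test_best_glide_closed_form():
    polar = GlidePolar(a=0.01, b=0.0, c=1.0)
    assert best_glide_speed(polar) == pytest.approx(10.0, abs=1e-9)


def test_best_glide_scaling_law():
    p1 = GlidePolar(a=0.01, b=0.0, c=1.0)
    p4 = GlidePolar(a=0.01, b=0.0, c=4.0, v_range=(6.0, 40.0))
    assert best_glide_speed(p4) == pytest.approx(2 * best_glide_speed(p1), rel=1e-9)


def test_best_glide_numeric_matches_golden_section_oracle():
    polar = GlidePolar(a=0.012, b=0.03, c=0.8)
    from scipy.optimize import golden

    v_star = golden(lambda v: polar.sink(v) / v, brack=(6.5, 8.0, 29.0))
    assert best_glide_speed(polar) == pytest.approx(v_star, abs=1e-6)


def test_maccready_closed_form_and_limit():
    polar = GlidePolar(a=0.01, b=0.0, c=1.0)
    assert maccready_speed(polar, 1.0) == pytest.approx(np.sqrt(200.0), abs=1e-9)
    assert maccready_speed(polar, 0.0) == pytest.approx(best_glide_speed(polar))


def test_maccready_monotone_in_climb():
    polar = GlidePolar(a=0.01, b=0.0, c=1.0, v_range=(6.0, 40.0))
    speeds = [maccready_speed(polar, z) for z in (0.0, 0.5, 1.0, 2.0, 3.0)]
    assert np.all(np.diff(speeds) > 0)


def test_negative_climb_clamps_to_zero():
    polar = GlidePolar(a=0.01, b=0.0, c=1.0)
    assert maccready_speed(polar, -2.0) == maccready_speed(polar, 0.0)


def test_invalid_polar_rejected():
    with pytest.raises(ValueError):
        GlidePolar(a=-0.01)


# --- RAFI -----------------------------------------------------------------


def _glide_with_airspeed(v):
    seg = FlightSegment(mode=MODE_GLIDE, start=0, end=10)
    seg.mean_airspeed = v
    return seg


def test_rafi_anchors_and_midpoint():
    polar = GlidePolar(a=0.01, b=0.0, c=1.0, v_range=(6.0, 40.0))
    v_bg = best_glide_speed(polar)
    v_mc = maccready_speed(polar, 1.0)
    assert rafi(_glide_with_airspeed(v_bg), 1.0, polar) == pytest.approx(1.0)
    assert rafi(_glide_with_airspeed(v_mc), 1.0, polar) == pytest.approx(0.0)
    mid = (v_bg + v_mc) / 2.0
    assert rafi(_glide_with_airspeed(mid), 1.0, polar) == pytest.approx(0.5)


def test_rafi_strictly_decreasing_in_observed_airspeed():
    polar = GlidePolar(a=0.01, b=0.0, c=1.0, v_range=(6.0, 40.0))
    v_bg, v_mc = best_glide_speed(polar), maccready_speed(polar, 1.5)
    vals = [rafi(_glide_with_airspeed(v), 1.5, polar)
            for v in np.linspace(v_bg, v_mc, 7)]
    assert np.all(np.diff(vals) < 0)


def test_rafi_zero_climb_undefined():
    polar = GlidePolar(a=0.01, b=0.0, c=1.0)
    with pytest.raises(ValueError):
        rafi(_glide_with_airspeed(11.0), 0.0, polar)


def test_rafi_ratio_definition():
    polar = GlidePolar(a=0.01, b=0.0, c=1.0)
    seg = _glide_with_airspeed(12.5)
    assert rafi(seg, 1.0, polar, definition="ratio") == pytest.approx(10.0 / 12.5)


# --- efficiency -----------------------------------------------------------


def _manual_pair(series):
    th = FlightSegment(mode=MODE_THERMAL, start=0, end=151, bird_id="T1")
    gl = FlightSegment(mode=MODE_GLIDE, start=151, end=252, bird_id="T1")
    characterize_segment(th, series)
    characterize_segment(gl, series)
    return [th, gl]


def test_efficiency_arithmetic():
    """900 m of gliding after a 150-s climb = 6.0 m per s of climb."""
    t = np.arange(252.0)
    x = np.r_[30 * np.sin(np.radians(18.0 * t[:151])),
              30 * np.sin(np.radians(18.0 * 150)) + 9.0 * (t[151:] - 150)]
    alt = np.r_[300 + 1.4 * t[:151], 300 + 1.4 * 150 - 0.75 * (t[151:] - 150)]
    s = series_from_xy(t, x, np.zeros(252), alt)
    segs = _manual_pair(s)
    # glide covers 100 steps of 9 m = 900 m; climb duration 150 s
    assert soaring_gliding_efficiency(segs, s) == pytest.approx(6.0, rel=0.01)


def test_no_qualifying_pairs_flagged():
    s = helix_track(duration=100)
    th = FlightSegment(mode=MODE_THERMAL, start=0, end=100)
    with pytest.raises(ValueError):
        soaring_gliding_efficiency([th], s)


def test_pair_gap_limit():
    s = helix_track(duration=300, climb=0.5)
    th = FlightSegment(mode=MODE_THERMAL, start=0, end=100, bird_id="T1")
    gl = FlightSegment(mode=MODE_GLIDE, start=150, end=250, bird_id="T1")  # 50-s gap
    pairs = thermal_glide_pairs([th, gl], s, max_gap_s=10.0)
    assert pairs.empty


# --- daily summaries ------------------------------------------------------


def test_straight_out_leg_straightness_one():
    t = np.arange(600.0)
    s = series_from_xy(t, 10.0 * t, np.zeros(600), np.full(600, 400.0))
    s.df["in_flight"] = True
    days = daily_summary(s, [], [])
    assert len(days) == 1
    assert days[0].straightness == pytest.approx(1.0)
    assert days[0].travel_distance_km == pytest.approx(5.99, rel=1e-3)


def test_out_and_back_straightness_uses_distance_until_max_displacement():
    """Returning along the same path keeps straightness at 1.0 because the
    denominator stops at the farthest point."""
    half = np.arange(300.0)
    x = np.r_[10.0 * half, 10.0 * 299 - 10.0 * (half + 1)]
    t = np.arange(600.0)
    s = series_from_xy(t, x, np.zeros(600), np.full(600, 400.0))
    s.df["in_flight"] = True
    days = daily_summary(s, [], [])
    assert days[0].straightness == pytest.approx(1.0, abs=1e-6)
    assert days[0].max_displacement_km == pytest.approx(2.99, rel=1e-3)


def test_no_flapping_bursts_gives_zero_proportion(small_segmented):
    track, segments = small_segmented
    from soartrack.preprocess import classify_bursts, compute_odba

    for b in track.bursts:
        compute_odba(b)
        b.flap_label = "passive"
    days = daily_summary(track.series, segments, track.bursts)
    assert all(d.flapping_proportion == 0.0 for d in days)
    assert all(np.isfinite(d.mean_odba) for d in days)


# --- foraging filter ------------------------------------------------------


def _day(travel, straightness, roost=5.0):
    return DailySummary(
        bird_id="b", date="2013-08-01", travel_distance_km=travel,
        max_displacement_km=20.0, straightness=straightness,
        flapping_proportion=0.0, mean_odba=1.0, n_thermals=5, n_glides=5,
        n_linear=0, soaring_gliding_efficiency=6.0, roost_distance_km=roost,
    )


@pytest.mark.parametrize("day,expected", [
    (_day(150.0, 0.2), True),     # ordinary foraging day
    (_day(250.0, 0.2), False),    # > 200 km travel excluded
    (_day(150.0, 0.8), False),    # straightness > 0.7 excluded
    (_day(150.0, 0.2, roost=90.0), False),  # too far from the roost
])
def test_foraging_day_filter(day, expected):
    assert foraging_day_filter(day) is expected


# --- TKE selection --------------------------------------------------------


def test_uniform_tke_returned_exactly():
    s = helix_track(duration=80)
    s.df["tke_1km"] = 1.2
    seg = FlightSegment(mode=MODE_THERMAL, start=0, end=80)
    assert thermal_selection_tke(seg, s) == pytest.approx(1.2)


def test_tke_equals_brute_force_mean():
    rng = np.random.default_rng(3)
    s = helix_track(duration=80)
    vals = rng.uniform(0.5, 2.0, len(s))
    s.df["tke_1km"] = vals
    seg = FlightSegment(mode=MODE_THERMAL, start=10, end=70)
    assert thermal_selection_tke(seg, s) == pytest.approx(vals[10:70].mean(), rel=1e-12)


def test_tke_bump_raises_value_above_background():
    from soartrack.synthetic import simulate_wind_field
    cfg = SimulationConfig(tke_background=0.8,
                           tke_bumps=((0.0, 0.0, 800.0, 1.0),))
    fld = simulate_wind_field(cfg, ((-3e3, 3e3), (-3e3, 3e3), (0, 1000), (0, 900)))
    s = helix_track(duration=80)
    from soartrack.wind import annotate_series
    annotate_series(s, fld)
    seg = FlightSegment(mode=MODE_THERMAL, start=0, end=80)
    assert thermal_selection_tke(seg, s) > 0.8
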