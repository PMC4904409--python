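# Methods

This note documents the models, algorithms and numerical choices behind
soartrack, what the synthetic data generator does and does not emulate, and
the design decisions taken where the underlying procedures are genuinely
open.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Flight model and segmentation

The package targets the soaring-gliding cycle of large raptors sampled at
1 Hz in flight.  A fix is *in flight* when its ground speed (step distance
over elapsed time, tolerant of dropped fixes) exceeds 2 m/s; isolated
single-fix state flips are removed by a 3-fix majority filter.  Analysis
operates per contiguous 1-Hz stretch; a time gap above 2 s always splits a
stretch and no window or difference ever bridges a gap.

**Vertical speed.** Raw vertical speed is the first difference of
altitude-above-ground over elapsed time.  It is smoothed by robust locally
weighted linear regression over a centred 5-s window: tricube distance
weights, two bisquare reweighting iterations on residuals scaled by six
times their median absolute value (falling back to the mean absolute value
when the median is zero, so isolated spikes on otherwise clean data are
still rejected).  Windows truncate at stretch edges.  The construction is
the standard robust-lowess one; on interior points of a uniform stretch it
agrees with `statsmodels` lowess (`frac = 5/n, it = 2`) to ~1e-14, which the
test suite uses as an independent oracle.  The smoother operates on the
differenced series, not on altitude — an explicit choice where either
reading is defensible; the sensitivity is limited because both reproduce
affine altitude profiles exactly.

**Thermal soaring.** Circling is detected geometrically: the step segment
ending at each fix is tested for proper intersection against every earlier
step within a 120-s trailing window (vectorized over index offsets, O(n·w)).
Overlapping intersection spans, and spans separated by at most 10 s, merge
into one candidate event; an event is a thermal iff it lasts more than 45 s
and gains altitude.  Two parameters extend the published rule set, both
config-exposed:

- *lookback 120 s*: loop periods are tens of seconds, so a 2-min window
  cannot miss circling while avoiding quadratic cost;
- *turning-core edge trim*: an intersection chain provably reaches a few
  seconds into the straight entry and exit legs (the first circle crosses
  the incoming glide line; the outgoing line crosses the circle), which
  contaminates climb-rate estimates.  Event edges are therefore dropped
  while their centred 5-s mean signed turn rate is below half the event's
  median turn rate — the same spirit as the trend-segment edge trimming
  below.  The smoothed turn statistic is used because per-step heading noise
  at 3-m GPS error is several degrees while sustained circling turns at
  ~18 deg/s.

**Gliding and linear soaring.** Outside thermals, maximal runs are grown in
which at least 90% of smoothed vertical-speed samples share one sign (zeros
count toward neither trend); descending runs are glides, ascending ones
linear soaring.  A run is abandoned only when no in-trend stretch within a
300-s horizon could restore the 90% fraction — a greedy scan with a hard
floor instead proved to split true glides whenever autocorrelated noise
clustered a few sign flips early in the run.  Run edges are then trimmed
greedily: while removing the first or last sample strictly increases the
in-trend fraction, the more profitable removal is applied.  Runs shorter
than 10 s (a parameter the trend rule needs but published procedures do not
state) are discarded.

**Characterization.** Per segment: duration and altitudinal change between
first and last fix, travel distance as the sum of step lengths, mean
vertical speed ≡ altitudinal change / duration (so climb rate is internally
consistent by construction), mean horizontal speed, and mean absolute
heading change per second.  Wind support and side-wind are computed for
glides only; side-wind is positive when the wind comes from the bird's left
(a convention the package fixes because signed side-wind means are otherwise
ambiguous).

## Wind, airspeed and circling geometry

Gridded U/V/TKE fields (x, y in a local planar frame; z above ground;
t in seconds; 1-km and 5-min default spacing) are interpolated
multilinearly; the kernel is a plain product-of-weights evaluation that
matches nested 1-D interpolation to a few ulp.  Spatial queries outside the
hull clamp to the edge (counted in the log); temporal extrapolation is an
error.  The 1-km TKE context of a fix is the mean over the corner nodes of
its enclosing horizontal cell (a radial average is a defensible alternative;
the cell is cheaper and equally local).

Airspeed is the ground-velocity vector minus the interpolated wind.
"Wind shear" of a thermal is operationalized as the mean horizontal wind
speed interpolated along the event — the quantity that tilts and drifts the
column — not a vertical wind-gradient; classes split at 2 and 6 m/s with the
middle interval closed ([0,2) low, [2,6] mid, (6,∞) high).

Circling direction is the sign of the summed signed heading change (net
turn below 180° is flagged indeterminate).  The lee/windward split of a
drifting thermal projects each fix, relative to the drifting column centre,
onto the wind axis: the downwind half is the lee side.  The centre is the
drift-compensated circle fit re-advected by the cumulative wind.  The
positional rule is primary; the flight-versus-wind angle (circular
difference between heading and wind origin, 0 = headwind, ±180 = tailwind,
positive = wind origin on the bird's left) is computed alongside.

**Circling radius.**  Positions are first de-drifted by subtracting the
cumulative interpolated wind, then each full 360° loop is fitted by the
algebraic Kåsa least-squares circle with one Gauss-Newton refinement step;
the event radius is the mean per-loop radius.  Uniform drift cancels exactly
(noise-free recovery to 1e-6 m); under 3-m GPS noise the estimator carries a
small positive bias of order σ²/R (≈ 0.25 m at R = 36 m), well inside the
tolerances used.

## Energy proxies

ODBA of a 3.8-s, 10-Hz burst subtracts the per-axis static component (the
whole-burst mean by default — bursts are short and disjoint, so there is no
within-burst drift to track) and averages the summed absolute dynamic
components.  Flapping classification is a transparent two-feature rule:
flapping iff ODBA exceeds 0.3 g and at least 25% of heave-axis spectral
power (DC removed) lies in the 3–5 Hz band.  This stands in for the
field-trained supervised classifiers used with real loggers, whose training
data are not reproducible; the thresholds are frozen in config and the rule
is validated only against the generator's synthetic bursts, which are built
to be separable (see limitations).

## Glide polar, speed choice and efficiency

The glide polar is a declared input, never hard-coded: a quadratic
`sink(v) = av² + bv + c` with a positive-curvature check and a valid
airspeed range (defaults a = 0.0115, b = 0, c = 0.93, giving a 9 m/s
best-glide speed typical of a large vulture).  Best-glide maximizes v/sink
(closed form √(c/a) at b = 0); the MacCready speed for expected climb z
maximizes cross-country speed v·z/(z + sink(v)) (closed form √((c+z)/a));
negative expected climb clamps to zero.  The risk-aversion index is
normalized by default, RAFI = (V_M − V_obs)/(V_M − V_bg) clipped to
[0, 1.2], anchored at 1 for best-glide and 0 for MacCready flight; a plain
ratio definition V_bg/V_obs is available behind config because the two
published verbal definitions conflict and the package does not silently
reconcile them.

Soaring-gliding efficiency pairs each glide with the thermal that ends at
most 10 s before it and reports glide travel distance divided by thermal
duration; the daily value is the mean over pairs.

Daily metrics: travel distance (sum of step lengths over all samples of the
day), maximum displacement from the day's first fix, straightness = maximum
displacement divided by the travel distance accumulated up to and including
the argmax fix, flapping proportion over in-flight bursts, mean ODBA, mode
counts.  The foraging-trip filter keeps days with travel ≤ 200 km,
straightness ≤ 0.7 and a start position within 60 km of the roost (the
roost-distance threshold is not published; 60 km is the config default).

## Inferential layer

Mann-Whitney-Wilcoxon U uses midranks; the two-sided p-value is exact (full
enumeration) for tie-free samples with n₁·n₂ ≤ 400, otherwise the
tie-corrected normal approximation.  ANCOVA fits response ~ factor +
covariate by OLS and reports the Type-II F for the factor.  The
shear-response analysis bins per-thermal adult-juvenile climb differences
into 1-m/s wind-shear bins (bins missing a class are dropped and logged) and
compares three least-squares models — constant, linear, quadratic — by AICc
with k = number of regression coefficients; adjusted R² = 1 − (1−R²)(n−1)/(n−k).
The unit of analysis for group tests defaults to per-individual means;
per-thermal pooling is available but off.  Tests are two-sided throughout
and no multiple-testing correction is applied.

Model-selection behaviour depends on the number of bins: with 9 one-m/s
bins the constant model resists overfitting strongly (win rate ≈ 0.86 on
pure noise) but a hump of the published size is detected in only ~half of
noisy replicates; ~33 quarter-m/s bins are needed before the quadratic wins
≥ 95% of the time at 25%-of-range noise.  The property tests therefore run
each claim at a bin count with adequate power (9 for the constant, 33 for
the quadratic).

## The synthetic generator

`simulate_track` builds, per day: morning/evening roost fixes at 600-s
cadence with near-zero speed; then an alternation of thermal climbs and
glides (plus occasional linear-soaring legs) at 1 Hz.  A thermal is a helix
of configured radius (default 35.9 m) and period (20 s) whose centre is
advected each second by the wind at current altitude; climb = updraft −
circling sink (defaults 1.5 − 0.1 = 1.4 m/s, per-thermal updrafts drawn with
SD 0.3); circling direction is random; entry and exit are tangent-continuous
with the adjoining glides.  Glides fly a fixed heading at the configured
airspeed (9 m/s) plus wind, sinking at 0.75 m/s, for a duration drawn around
192 s; an optional `efficiency_target` couples each glide's duration to its
preceding climb so the true glide-distance/climb-time ratio is an exact
injected value.  Altitude is softly bounded (glides truncate below 80 m,
climbs above 2500 m).  Defaults are calibrated once to the summary
statistics of the griffon-vulture study system the package targets (thermal
duration 150 ± 30 s, the climb/sink/radius values above, adult per-burst
flapping probability 0.02) and are study conditions, not tuning knobs.

ACC bursts are emitted every 60 s of flight: gravity plus white noise
(SD 0.05 g) on all axes, and for flapping bursts (Bernoulli per burst) a
1-g, 4-Hz sinusoid on the heave axis.  GPS noise is added last: stationary
AR(1) Gaussian error per component with 3-m marginal SD and a 60-s
correlation time.  The correlation time is a calibration: real logger error
is strongly autocorrelated, and 60 s puts the 1-Hz differenced
vertical-speed noise near 0.55 m/s, consistent with the premise that climb
and sink signs are recoverable after 5-s smoothing.  White noise of the
same marginal SD would make 1-Hz vertical-speed signs essentially random
(SD 4.2 m/s) and no trend-based segmentation could operate.

What the generator does **not** emulate — and hence what passing recovery
tests do and do not show: thermal life cycles, spatially varying updraft
profiles (except an optional lee-side boost used to test the lee/windward
machinery), terrain (altitude is above flat ground), airframe dynamics
(bank-dependent sink, gusts), GPS dropouts, multi-bird files, or realistic
ACC signatures beyond the separable sinusoid-vs-noise contrast.  Recovery
results demonstrate that the pipeline measures what the model generates at
realistic noise levels; they do not validate the ACC classifier or the
segmentation against field-labelled data.

## Numerical choices and degenerate inputs

- Local planar frame: spherical azimuthal-equidistant projection about a
  fixed origin; sub-millimetre round trip at foraging scales, so simulated
  geometry survives the lon/lat encoding exactly.
- Half-open index ranges everywhere; durations are elapsed time between a
  segment's first and last fix.
- Zero smoothed vertical speed counts toward neither trend sign.
- Singleton wind-grid axes are padded so interpolation stays defined;
  degenerate extents are rejected.
- Circle fits need ≥ 5 fixes per loop; events with less than one full loop
  have no radius and are flagged, not guessed.
- All-identical pooled samples give U = n₁n₂/2 and p = 1 directly (the tie
  correction would otherwise divide by zero).
- Malformed file rows are counted and logged, never silently dropped;
  out-of-range coordinates and non-monotone timestamps are integrity errors.
- End-to-end determinism: one `numpy` Generator seeded from config drives
  the simulation; rerunning the pipeline with the same config and seed
  writes bit-identical tables (checked in the tests).

## Problem sizes

The recovery analyses run at desk scale by design: 20 bird-days
(~140,000 fixes, ~400 thermals) for the segmentation and vertical-speed
recoveries, 30 days for the flapping proportion, 100 thermals for the
radius, 200 replicates for the model-selection rates.  These sizes put
Monte-Carlo error well inside every tolerance used while keeping the whole
suite and the acceptance script in the tens of seconds.

## Known limitations

- The ACC flapping classifier is a stand-in with frozen thresholds; absolute
  ODBA values of synthetic bursts are not calibrated to real flight (passive
  bursts carry only sensor noise, so daily mean ODBA is far below field
  values and is meaningful comparatively only).
- Thermal detection assumes circling produces 2-D self-intersections within
  120 s; straight-line thermalling along a ridge (no loops) is classified as
  linear soaring by design.
- The published AICc values of the shear-response comparison cannot be
  reproduced without the underlying binned data; only the printed hump
  coefficients are checked, by refitting the function from its own values.
- Wind "shear" is a horizontal wind speed at thermal altitude; users wanting
  a true vertical gradient must compute it from the profile themselves.
- Single-bird series are the unit of processing; multi-bird studies loop the
  pipeline per bird.
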