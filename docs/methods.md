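# Methods

`activegaze` implements the measurement and analysis chain of a
real-world active visual-search experiment: a searcher walks freely in a
3 x 4 m arena furnished with 3 tables and 6 wireframe cages, looking for a
small target object among distractors, while a head-mounted eye tracker
samples eye-in-head gaze at 50 Hz and a motion-capture system tracks the
head rigid body at 120 Hz.  This note describes the models, conventions
and numerical choices behind each stage, what the synthetic searcher does
and does not emulate, and the known limitations.

## Coordinate frames and conventions

The world frame is right-handed and z-up: x–y span the arena floor, z is
elevation, origin at an arena corner.  Head orientation is a unit
quaternion (scipy scalar-last order, `qx qy qz qw`); the head's forward
axis is local +x by default and is configurable per recording source,
because marker-mount orientation in mocap exports is arbitrary.
Eye-in-head gaze is a unit vector in the head frame (+x ahead, +y to the
wearer's left, +z up); eye-in-world is the head rotation applied to it.
Head attitude decomposes intrinsically as yaw (pan about z), then pitch
(flexion; negative = tipped down), then roll (lateral bend; positive =
toward the wearer's right).  At the gimbal configuration (|pitch| = 90°)
the roll := 0 convention applies and the result is flagged.  Angles cross
every API boundary in degrees; internal math uses radians.  All lengths
are meters.

## Arena geometry

Tables are 1.14 x 0.70 m, 0.70 m tall; cages are 0.30 m cubes resting on
tables, with per-face cover state: `covered` (opaque panel), `wire`
(see-through mesh) or `open` (exactly one per cage).  Every layout has
one stacked cage pair, one side-by-side pair and two singles.  With these
dimensions a cage top sits at 1.00 m and the stacked top at 1.30 m;
the strict ordering table < cage top < stacked top is what the analyses
rely on.  Four layout files are shipped; since only the structural
constraints of the arena are documented exactly (box counts, dimensions,
stacking, start corner), the furniture coordinates in these files are
this package's choice, made once so that every cage keeps a walkable
frontal viewpoint.  `validate_layout` returns the violated rules rather
than raising, so layout files can be linted.

Objects are points with a size scalar (extent 1.5–15.1 cm); their 3D
shape is not modelled.  A target placement sits on a table top, inside a
cage (on its floor) when the cage carries another cage, or on top of a
cage otherwise, giving the four elevation levels used by the
head-elevation analyses.

## Stream merging

The merged series has one row per gaze timestamp.  Head position is
linearly interpolated and head orientation slerped (shortest arc) between
the bracketing 120 Hz samples; gaze samples outside the head timeline are
flagged invalid, never extrapolated.  A gaze sample is valid when both
eyes report valid and the direction is finite.  Runs of invalid gaze are
interpolated (componentwise-linear on the direction, then renormalized)
when the bracket from the last valid sample to the first valid one spans
at most 75 ms, inclusive; longer runs stay missing.  The componentwise
interpolation differs from a great-circle path by far less than sensor
noise at these gap lengths (≤ 4 samples) and is documented here for
reproducibility.  Subject exclusion uses the raw validity fraction
(gap-filled samples do not count) with a strict < 65 % rule.

## Event detection (I-VT)

Angular velocity is the two-point estimate angle(e_i, e_{i+1}) / Δt on
adjacent eye-in-head samples, with no smoothing window.  Maximal runs of
sample pairs below 30 °/s become fixations, subject to a minimum duration
of 60 ms (3 samples at 50 Hz — the threshold the upstream classifier used
is not documented, so this default is explicit and configurable); the
intervals between consecutive fixations within one contiguous valid block
are saccades.  Missing-gaze runs break events: no fixation or saccade
spans a gap.  Each fixation is summarized by the renormalized vector mean
of its gaze directions, the arithmetic mean head position and the
quaternion mean of its head orientations (largest-eigenvector method with
hemisphere alignment, via scipy's rotation mean).  Duration comparisons
carry a 1 ns slack because equal grid times can differ by one float ulp
at large absolute timestamps.

Outlier removal (used for durations globally and for head angles per
subject) is a single pass: values more than k = 3 sample standard
deviations from the mean of the full list are removed, with no
re-iteration; zero variance removes nothing.

## Saccade decomposition

For a saccade from fixation A to fixation B:

* eye-in-head amplitude = angle between the mean eye-in-head directions;
* head amplitude = angle between the world-frame head forward axes;
* eye-in-world amplitude = angle between the two eye-in-world vectors.

The eye contribution is the additive share eye/(eye+head), which makes
"the head contributed more" identical to head amplitude > eye amplitude;
the alternative eye/world ratio can be computed from the same fields.
"Cancellation" is operationalized as opposite signs of the azimuthal
displacement of the eye-in-head direction (head frame) and of the head
forward axis (world frame); zero eye displacement never counts.  Both
definitions are isolated in single functions so they can be swapped.
A saccade is "head-minimal" when the head amplitude is below 1°.

Note that eye-in-world ≤ eye-in-head + head amplitude is *not* an
identity: the head amplitude measures only the forward-axis displacement
and understates rotations with a twist component.  The true bound uses
the geodesic angle of the relative head rotation, and that is what the
test suite asserts.

## Look-at classification and visibility

Each fixation's gaze ray (origin: mean head position, a cyclopean eye at
the head-marker origin; direction: eye-in-world) is cast against all
boxes with the slab method; the nearest hit names the look-at target,
otherwise the fixation is "environment".  A hit on a covered face counts
as looking at that box — the subject sees its surface; the alternative
(skipping covered-face entries) is selectable.  Visibility of a target
*inside* a box is the separate operation: the eye-to-object segment must
cross no covered cage face and no solid table volume; wire and open faces
are transparent.  The visibility eye point sits 0.10 m below the standing
head-marker height (the marker sits above the eyes; the offset is a
declared constant).

Revisit counting drops environment labels (they do not end a visit),
collapses consecutive duplicates, and counts every compressed entry whose
label appeared earlier; `unique_revisited` counts distinct labels with at
least one return.

## Trial metrics and hotspots

Distance travelled is the 3D polyline length of the merged-rate head
track (a fixation-hop variant exists for sensitivity checks).  The
moved-out-of-start index is the first fixation strictly more than 0.30 m
from the first fixation's head position.  Hotspots are DBSCAN clusters of
fixation head positions on the floor plane with eps = 0.15 m and a core
threshold of 2 % of the pooled points (rounded up, floored at 2 so an
isolated point is never a cluster); each cluster carries the look-at
histogram of its member fixations.  The 2 % denominator is the pooled
clustered set (per layout, across subjects).

## Statistics

Mixed models are random-intercept fits (subject as grouping factor) by
REML; fixed-effect p-values use the normal approximation to the Wald
statistic, and simulation shows the resulting slope test holds its
nominal type-I rate (≈ 0.048 at α = 0.05 over 1,500 null replicates at
72 subjects x 12 trials).  ICC = σ²_subject / (σ²_subject + σ²_residual).
Skewed trial metrics are log-transformed (natural log; log1p for counts
that can be zero).  The visibility x set-size analysis is a two-way OLS
ANOVA on target-present trials with type-II sums of squares, partial eta
squared computed as SS_effect / (SS_effect + SS_residual), and Tukey HSD
contrasts over the factor cells.  Accuracy, binary per trial, is averaged
per subject x presence x set-size cell and analysed with a
repeated-measures two-way ANOVA.  Orientation effects on roll, pitch and
relative head elevation use deviation (sum-to-zero) coding after per-subject
3-SD angle cleaning; the reference category's deviation is reported as
minus the sum of the others.  Head elevation is measured relative to the
standing height, the maximum head elevation across the session after
3-SD spike removal, and regressed on target surface elevation by OLS
with Pearson r.

## The synthetic searcher

The simulator is a measurement-chain test harness, not a model of search
behaviour.  A scripted searcher starts in the arena corner, scans twice,
then visits furniture: walk to a frontal viewpoint of the next box
(detouring around tables), crouch toward the height of the viewed
surface, fixate several jittered points on it, and continue; on reaching
the target it fixates the target three times and responds.  Response
errors are scripted with the study's observed error profile (12.5 % miss,
5.8 % false alarm).  While walking, gaze alternates between
ahead-of-travel holds and glances at furniture, with small head yaw
adjustments at each shift.  Each gaze shift splits between head and eye
by a random gain (mean 1, SD 0.35): gains above 1 make the eye
counter-rotate, producing cancellation cases.

Timeline grids make zero-noise recovery exact rather than approximate:
eye-channel event boundaries lie on the 50 Hz grid (fixations are
multiples of 20 ms; scripted saccades last 40 ms and move ≥ 2.5°, so the
inner sample pair always exceeds 30 °/s), head-pose corners (walk
waypoints, head-rotation windows inside saccades) lie on the 120 Hz grid
so linear/slerp resampling at gaze timestamps is lossless, and walk
events begin and end on the common 0.1 s grid.  Gaze shifts below 2.5°
would be invisible to the detector, so the script never emits them: a
proposed small shift is re-aimed or absorbed into the running hold.
Ground-truth look-at labels are evaluated with the ray caster at each
scripted fixation's mean head position (the ray caster itself is verified
against a dense ray-marching oracle, keeping the check meaningful).

Behavioural defaults were set once to land in the regime of the real
task (target-present trials ≈ 40–60 fixations, 7–9 m, 16–20 s;
target-absent roughly double; look-at share near one half; revisit counts
≈ 6 present / 16 absent).  Present-trial durations run somewhat shorter
and environment-fixation shares somewhat higher than in real searchers;
the defaults are generator settings, not assertions about human data.

Sensor degradation is explicit and separate: gaze noise is an isotropic
tangent-plane offset whose magnitude has mean `gaze_sd` (default 1.29°,
the tracker's printed precision while walking) and which evolves as an
AR(1) process (ρ = 0.985 per sample).  The temporal correlation reflects
slippage-dominated tracker error: the apparent gaze drifts around the
true line of sight.  White noise of the same magnitude would alias into
sample-to-sample velocities far above 30 °/s and no fixation would ever
be detected — a property of the detector, not of the simulator.  Head
positions get iid Gaussian noise (default SD 0.2 mm).  Dropouts are
two-state-Markov runs with configurable stationary rate and mean/max run
length, marking both eyes invalid.

What the simulator does not emulate: smooth pursuit and VOR during
locomotion (eye-in-head is held constant while walking), torsional eye
movements, head roll (scripted roll is zero; roll analyses are exercised
with injected datasets), learning across trials, clock drift between
devices, and asymmetric per-eye dropouts.  Passing recovery tests
therefore demonstrate the correctness of the measurement chain on
behaviour-like signals, not the realism of the behaviour itself.

## Problem sizes

The shipped analyses use sizes chosen to exercise the full design while
staying desk-scale: the acceptance script simulates one subject per
layout x version cell (24 subjects x 12 trials = 288 trials) at the
tracker's noise levels with ~14 % dropouts, reproducing the full 4 x 6
counterbalancing at a third of the study's subject count; statistical
calibration uses the study's size (72 x 12) with 100 coverage and 400
null replicates in the script and 200/1,000 in the test suite.

## Known limitations

* The I-VT detector is deliberately minimal (no smoothing window, no
  saccade-amplitude floor); exact event-level agreement with proprietary
  vendor classifiers is not expected, only statistical agreement.
* The external-export adapter is verified against synthetic exports
  written in the same dialect; column names of real exports may need a
  custom mapping (`gaze_map` / `head_map` arguments).
* Look-at labels use a cyclopean ray from the head-marker origin; no
  per-eye vergence model.
* Hotspot membership near the eps boundary is sensitive to single-point
  perturbations, as with any density-based clustering.
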