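# activegaze

Measurement and analysis chain for **real-world active visual search**:
from synchronized mobile eye-tracking (50 Hz eye-in-head gaze) and
motion-capture head pose (120 Hz) to fixations, eye/head saccade
decomposition, 3D look-at classification against an occluded arena,
trial-level search metrics, and mixed-model statistics.  A scripted
synthetic searcher generates ground-truthed recordings, so every stage of
the chain is testable without any data download.

## Who this is for

Researchers analysing head-free visual search in instrumented spaces: a
subject walks freely in a 3 x 4 m arena furnished with 3 tables and 6
wireframe cages (some faces covered to create occlusion), searching for a
small target object.  The pipeline answers where the searcher looked
(which table or cage each fixation landed on), how gaze shifts split
between eye and head, how far they walked, how often they revisited
locations, and how these measures depend on target presence, set size,
start-visibility and target orientation.

## The core quantities

With head orientation `R` (quaternion, forward axis +x) and eye-in-head
direction `e` (unit vector), the gaze direction in the world is
`g = R e`.  For a saccade between fixations A and B the decomposition is

    eye-in-head amplitude  = angle(e_A, e_B)
    head amplitude         = angle(R_A x̂, R_B x̂)
    eye-in-world amplitude = angle(R_A e_A, R_B e_B)
    eye contribution       = eye / (eye + head)

Fixations are velocity-threshold (I-VT) events: maximal runs of samples
whose two-point eye-in-head angular velocity stays below 30 °/s.  Look-at
labels come from casting each fixation's world gaze ray (origin: mean
head position) against the axis-aligned furniture; the nearest hit wins,
else the fixation is "environment".  Mixed models are random-intercept
fits with subject as the grouping factor (REML, Wald p-values); see
`docs/methods.md` for every convention and numerical choice.

## Worked example

Simulate one target-present trial, add tracker-level noise, and run the
measurement chain:

```python
from activegaze import builtin_layout, generate_trial, process_recording
from activegaze.simulate import TrialCondition, add_sensor_noise

layout = builtin_layout(1)
condition = TrialCondition(
    target_present=True, set_size=40, visible_from_start=False,
    target_orientation="front_up", target_surface="C3",
)
recording, truth = generate_trial(layout, condition, seed=7)
noisy = add_sensor_noise(recording, gaze_sd=1.29, head_pos_sd=0.0002, seed=7)
result = process_recording(noisy, layout, conditions={1: condition})

import numpy as np
m = result.metrics.iloc[0]
print(f"response time      : {m['response_time']:.2f} s")
print(f"fixations          : {m['n_fixations']} "
      f"({m['n_lookat_fixations']} on furniture, {m['n_environment_fixations']} environment)")
print(f"distance travelled : {m['distance']:.2f} m")
print(f"revisits           : {m['revisits']}")
amps = [s.decomposition for sc in result.saccades for s in sc]
print(f"mean eye-in-head amplitude : {np.mean([d.eye_in_head_amp for d in amps]):.1f} deg")
print(f"mean head amplitude        : {np.mean([d.head_amp for d in amps]):.1f} deg")
print(f"mean eye-in-world amplitude: {np.mean([d.eye_in_world_amp for d in amps]):.1f} deg")
print(f"scripted fixations: {truth.true_fixation_count}, detected: {m['n_fixations']}")
```

prints

```
response time      : 26.36 s
fixations          : 69 (35 on furniture, 34 environment)
distance travelled : 11.39 m
revisits           : 11
mean eye-in-head amplitude : 20.3 deg
mean head amplitude        : 32.9 deg
mean eye-in-world amplitude: 42.0 deg
scripted fixations: 69, detected: 69
```

The searcher took 26 s and 69 fixations to find a target that was not
visible from the start corner, walking 11.4 m and revisiting furniture
11 times; head rotations carried more of each gaze shift than the eyes
(32.9° vs 20.3° on average).  Even at 1.29° gaze noise the detector
recovers exactly the 69 scripted fixations; at zero noise the whole
chain — fixation count, look-at sequence, amplitudes, distance —
reproduces the script exactly, which is the package's central
self-check.

## Command line

```bash
activegaze simulate --out data/ --subjects 4 --trials 12 --seed 1
activegaze metrics  --data data/ --out tables/
activegaze report   --metrics tables/trial_metrics.csv
```

`simulate` writes per-subject `gaze.csv` / `head.csv` / `markers.csv`
plus ground truth; `metrics` runs merge → events → look-ats → trial
metrics and emits the analysis tables (including `scanpath_export.csv`
for external plotting and `hotspots.csv` with DBSCAN head-position
clusters); `report` prints the mixed-model and ANOVA summaries.

Recordings exported by other acquisition software can be ingested with
`activegaze.io.load_deposited_export`, which maps external column names
onto the same containers (gaze-point-only exports are supported via
`directions_from_points`).

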