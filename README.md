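# liftchar

Offline detection and characterization of box-lifting activity from
full-body wearable-sensor kinematics.

Occupational lifting is a leading cause of musculoskeletal injury, and risk
models such as the revised NIOSH lifting equation need per-lift parameters —
where the load started and ended, how far from the body it was held, how much
the lifter twisted, what posture they used. Full-body inertial motion-capture
suits can deliver the underlying kinematics outside the lab, but somebody
still has to find the lift in the recording and turn joint trajectories into
those parameters. `liftchar` is that somebody: it consumes fused kinematics
(segment positions/velocities/accelerations, joint angles, center of mass,
hand/foot positions) for pre-segmented single-lift trials and produces lift
windows, geometric lift parameters, a per-lift feature pool, and
subject-independent classification of posture, twist direction, vertical
movement and load weight.

Because raw suit recordings are rarely shareable, the package also includes a
seeded synthetic-trial generator that emulates a shelf-lifting protocol
(floor/knee/chest/head levels, squat vs. stoop, 45° left/right twists,
3 vs. 10 kg loads) with exact ground truth, so the whole pipeline is testable
end to end.

## The method

1. **Lift detection.** For each frame the mean distance from the center of
   mass (COM) to the two hands is computed,
   `d(t) = (‖p_L(t) − c(t)‖ + ‖p_R(t) − c(t)‖)/2`. Balance keeps the COM over
   the feet, so the hands are furthest from the COM at grasp and release. The
   signal is smoothed with a centered 30-frame moving average and the two most
   *topographically prominent* local maxima become the start and end of the
   lift.
2. **Lift parameters.** With the hands midpoint taken as the object position:
   signed asymmetry (twist) angle between the facing direction — the
   normalized sum of the foot headings — and the feet→hands floor-plane
   direction (counterclockwise from above is positive); object height above
   the floor at both endpoints; vertical displacement (end − start, so
   floor→chest = +1.08 m at the reference geometry); horizontal feet→object
   distance; and duration.
3. **Features.** A 223-entry pool per lift: 28 joints × 3 axes of joint
   movement `θ_end − θ_start` (84), their magnitudes (84), mean absolute
   velocity and acceleration of 23 segments (46), and the 9 lift parameters.
4. **Selection and classification.** Diagonal neighborhood component analysis
   (NCA) weights each feature; features within 2% of the top weight are kept,
   minus manual exclusions that would leak protocol artifacts. Classifiers are
   k-nearest-neighbor (posture k=30, asymmetry and vertical movement k=10) and
   Gaussian naive Bayes with uniform priors (weight), validated with
   subject-independent 5-fold cross-validation: folds partition participants,
   so test subjects are never seen in training.

## Worked example

```python
from liftchar import (LiftSpec, generate_trial, detect_lift,
                      detection_error, estimate_parameters)

spec = LiftSpec("floor", "chest", posture="squatting", twist="left",
                weight=10, noise_sd=0.005, seed=42)
trial, truth = generate_trial(spec)

window = detect_lift(trial)                      # peak-prominence detection
print(detection_error(window, truth.true_window))
print(estimate_parameters(trial, window))
```

Output:

```
(-0.050000000000000266, 0.033333333333333215)
LiftParameters(asym_start=-0.13140128326359615, asym_end=44.24041313383901,
asym_max=44.24041313383901, asym_diff=44.37181441710261,
height_start=0.2940375945565954, height_end=1.3743956324988469,
vertical_displacement=1.0803580379422515, horiz_start=0.2968221232094983,
horiz_end=0.44514095558887046, duration=2.6)
```

The detector found the lift within 0.05 s of the truth. The parameters read:
the lift started 0.29 m above the floor and ended at 1.37 m (the floor→chest
reference heights are 0.30 m and 1.38 m; the residual is the 5 mm sensor
noise), displaced the object +1.08 m upward, was held 0.30–0.45 m in front of
the feet, and twisted ≈ +45° to the left at its end — exactly the shelf
offset of the protocol.

The same pipeline scales to whole experiments:

```python
from liftchar import ProtocolSpec, iter_dataset, feature_table, cross_validate

table = feature_table(iter_dataset(ProtocolSpec(master_seed=7)))  # 1440 lifts
report = cross_validate(table, "posture")     # published features, KNN k=30
print(f"{report.accuracy:.2f}%")              # -> 100.00% on synthetic data
```

A `liftchar` command-line tool wraps the same functions
(`liftchar simulate | detect | characterize | extract-features | crossval`).

## Layout

- `src/liftchar/trial_model.py` — trial data model, CSV/YAML I/O, validation,
  downsampling
- `src/liftchar/synthetic_lifts.py` — minimum-jerk trial generator, protocol
  census, dataset streaming
- `src/liftchar/lift_detection.py` — COM–hands distance, smoothing, peak
  prominences, window detection
- `src/liftchar/lift_parameters.py` — asymmetry/height/displacement/distance
  geometry and reference values
- `src/liftchar/feature_extraction.py` — the 223-feature pool and published
  feature sets
- `src/liftchar/classify_cv.py` — diagonal NCA, KNN/naive Bayes,
  subject-independent cross-validation
- `docs/methods.md` — modeling assumptions, parameter choices, limitations
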