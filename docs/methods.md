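# Methods

This note documents the models and numerical choices behind `liftchar`: what
each stage assumes, which parameters matter and why their defaults are what
they are, what the synthetic generator does and does not emulate, and the
known limitations.

## Data model and conventions

A trial is a pre-segmented recording of exactly one two-handed lift, sampled
at a constant rate (60 Hz is the analysis default; recordings made at higher
rates are decimated with `downsample`, plain frame-dropping with no
anti-alias filter — the signals of interest are far below the Nyquist limit
at 60 Hz).

Fixed conventions, chosen once so all geometry is testable:

- right-handed axes, +Z up, floor plane = XY, +X the nominal forward
  direction of a participant at the origin;
- frames are 0-based; a lift window is half-open `[start, end)`; times are
  `frame / sample_rate`. The "end-of-lift state" used for endpoint
  quantities is therefore frame `end − 1`, and a window's duration
  (`(end − start)/fs`) exceeds the generator's nominal carry phase by exactly
  one frame period;
- joint angles in degrees. Axis `ax1` extends forward in the facing
  direction, `ax2` is vertical while standing, `ax3` is the lateral
  (flexion–extension) axis;
- the registries carry 23 segments and 28 joints: the 22 anatomical joints of
  a standard full-body skeletal model plus 6 ergonomic segment-pair angles
  (head/arm orientation relative to T8, pelvis–T8, and pelvis/T8 relative to
  vertical). Vendor joint lists are not public, so the registry is a
  documented stand-in; its size and naming are what the feature pool depends
  on, not its anatomical completeness.

Trial tables round-trip through CSV with shortest-repr floats and are parsed
back with round-trip float precision, so save → load → save is byte-stable.

## Lift detection

The detector assumes (a) one lift per trial, (b) hands starting and ending
relaxed at the sides, and (c) balance keeping the COM over the feet, so the
COM-to-hands mean distance peaks at grasp and at release.

- **Smoothing**: centered moving average, default window 30 frames (0.5 s at
  60 Hz). The window shrinks symmetrically at the series edges
  (radius `min(window // 2, i, n − 1 − i)`), which keeps the output length
  equal to the input and introduces no phase lag; a causal filter would bias
  both detected times late.
- **Peaks**: local maxima strictly greater than their neighbours; a flat
  maximal run is represented by the floor of its midpoint. Prominence is
  topographic: height minus the higher of the two minimal saddles toward
  higher terrain, series ends acting as boundaries; a peak at the global
  maximum is measured from the global minimum. Peak finding is backed by
  `scipy.signal`; the global-maximum rule is applied on top of it, and the
  whole computation is checked against a brute-force O(n²) saddle search in
  the tests.
- **Selection**: the two most prominent peaks, prominence ties broken toward
  the earlier frame; the earlier peak is the start. Fewer than two peaks
  raises a "no lift found" error — this occurs only on degenerate inputs
  (e.g. a constant distance signal), not on well-formed lifting trials.

A documented failure mode is reproduced by the generator's `false_start`
flag: if the lifter reaches to the object early and holds, the distance
signal forms a plateau with no local maximum left at the true start, and the
detected start lands on the plateau while the end remains accurate.

## Lift parameters

The hands midpoint is taken as the object position, exactly as the
estimators' premise requires (no grasp-offset model). The facing direction is
the normalized vector sum of the two foot headings; a circular mean of
heading angles differs only in degenerate configurations and is not used.
The asymmetry angle is the signed floor-plane angle from facing to the
feet-midpoint→hands-midpoint direction, counterclockwise-from-above positive
(a left twist), range (−180°, 180°]. Vertical displacement is end height
minus start height, making a floor→chest lift at the reference geometry
+1.08 m; this matches the sign convention of the reference-displacement
table the package ships (`reference_displacement`).

Reference geometry: shelf heights 0 / 0.54 / 1.08 / 1.57 m for
floor/knee/chest/head plus a 0.30 m hand-to-crate-bottom offset, giving
nominal hand heights 0.30 / 0.84 / 1.38 / 1.87 m; nominal horizontal rest
distances 0.30 / 0.50 / 0.45 / 0.45 m.

## Feature pool

223 entries per lift: 84 per-axis joint movements (`θ_end − θ_start`),
84 magnitudes, 23 segment mean absolute velocities, 23 mean absolute
accelerations, 9 lift parameters. The trunk-vs-vertical posture feature
(`trunk_inclination_max`) sits outside the pool: the pool enumeration is
complete at 223 without it, so it is exposed as a derived trial quantity and
included in the published posture feature set. It uses the *maximum* trunk
inclination over the window because posture differences peak mid-lift, not at
the endpoints; start/end variants would under-report stooping.

Published per-subproblem sets (sizes 7/3/3/3):

- posture: `trunk_inclination_max` + |flexion–extension movement| of both
  knees, both shoulders, both hips;
- asymmetry: asymmetry difference, largest asymmetry, T9–T8 movement about
  the forward axis;
- vertical movement: vertical displacement + endpoint heights;
- weight: mean absolute speed of the two hands and the head (three features;
  the hands contribute one feature each).

Manual exclusion lists accompany the selection step: for the weight
subproblem the largest twist angle, the pelvis–T8 movement about the vertical
axis and the horizontal endpoint distances are removed (in the emulated
protocol all light lifts are straight chest/floor lifts, so those features
would classify the protocol, not the load); for posture the endpoint heights
are removed (hand height should not indicate squat vs. stoop).

## Feature weighting and classifiers

- **Diagonal NCA.** Learns one nonnegative weight per feature by maximizing
  the expected leave-one-out accuracy under the softmax neighbour
  distribution with the weighted L1 metric `d_w(x,y) = Σ_r w_r² |x_r − y_r|`,
  minus an L2 penalty `λ Σ w_r²` (default `λ = 1/n`). Features are
  standardized on the fitting rows; optimization is L-BFGS-B from all-ones
  weights with an analytic gradient and per-row softmax stabilization, and is
  deterministic. The pairwise-difference tensor is O(n²·d) memory, which is
  fine at selection scale (hundreds of rows) but not for very large tables.
  This is a hand-written component: general-purpose libraries provide NCA as
  a full linear transform, not as per-feature relevance weights.
- **Selection.** "Within 2% of the top weight" (`w ≥ 0.98·max w`) is the
  default reading of the relative threshold; a top-fraction-by-count mode is
  available as an alternative (`mode="count"`).
- **KNN.** Euclidean distance in standardized feature space (training-fold
  statistics only; standardization is on by default because the pool mixes
  degrees, meters and m/s, and is exposed as a switch). Vote ties break by
  the smallest summed distance among tied labels, then lexicographically —
  fixed rules so predictions are reproducible. Neighbour search is backed by
  scikit-learn; the vote is implemented here to honour the tie-break rules.
- **Gaussian naive Bayes.** Uniform class priors regardless of class
  frequencies (the emulated protocol has a 4:26 light:heavy imbalance, and
  frequency priors would simply vote for the majority). Per-class variances
  are floored at `1e-9 ×` the pooled variance; a class-constant feature
  triggers a degenerate-model warning and is treated as uninformative.
  Log-posterior ties break lexicographically.
- **Cross-validation.** Folds partition *participants* (shuffled, dealt into
  near-equal folds: 24 participants into 5 folds gives 5,5,5,5,4), so test
  subjects never contribute to standardization, weighting or training.
  Vertical-movement rows outside the six main source→destination categories
  are excluded from that subproblem (too few samples per extra category).
  Accuracy is the confusion-matrix trace over the total, in percent.

## Synthetic generator

The generator emulates a shelf-lifting laboratory protocol: 30 main lift types
(4 levels, squat/stoop/neither, left/right/straight 45° twists, 3 vs. 10 kg)
× 2 repetitions × 24 participants, per-participant order randomization and
body-size scaling (±7%), one lift per ~7.7 s trial with a ~2.5 s carry.

Construction, in the order the trial unfolds: rest (hands at the sides,
below the pelvis) → minimum-jerk reach to the source grasp point, arriving
exactly at the true start frame → minimum-jerk carry from source to
destination → return to rest. Phase boundaries are snapped to whole frames so
endpoint geometry is exact at the ground-truth frames when `noise_sd = 0`.
The participant faces the lower endpoint; the higher endpoint is rotated
±45° about the vertical axis through the feet midpoint for twisting lifts,
so mirroring left↔right negates the true asymmetry exactly.

Specific modeling choices:

- **Distance peaks by construction.** Mid-carry the object is pulled toward
  the COM (the COM→object vector is shrunk by `0.45·sin(πτ)`), so the
  COM–hands distance has exactly one peak at grasp and one at release. The
  pull-in must act on the full 3D vector: a purely horizontal pull-in fails
  for chest→head lifts, where the overhead object keeps increasing the
  vertical COM–hand gap and the grasp peak would vanish.
- **Posture profiles.** Joint amplitudes are driven by how low the object is
  (a depth factor from the nominal hand height). Squatting: knee/hip flexion
  dominant (130°/100° at full depth) with small trunk inclination (20°);
  stooping: trunk inclination dominant (68°) with near-straight knees (12°);
  "neither" (chest↔head lifts) sits between but at near-zero depth. These
  produce the separation the posture features rely on.
- **Load effect.** Weight changes only speed, never geometry: 3 kg lifts run
  the carry 0.85× as long as the nominal duration. This mirrors the premise
  that load is kinematically weak — on real data weight classification was
  close to chance, and the generator is not designed to make it easy.
- **Noise model.** Positions get isotropic Gaussian noise (`noise_sd`,
  default 5 mm — the scale of fused-IMU position jitter). Velocities and
  accelerations are finite differences of the *noise-free* trajectories plus
  scaled noise (4× and 20× `noise_sd`), emulating the smoothed kinematics a
  fusion engine outputs; differentiating noisy positions would add a
  ~0.4 m/s noise floor to mean-speed features that fused kinematics do not
  show. Joint angles get jitter of 100°·`noise_sd` (0.5° at the default).
- **Durations.** Nominal carry 2.5 s, pre-rest 1.2 s, reach/return 1 s each,
  post-rest 2 s (≈ 7.7 s trials); per-trial jitter of ±5% (carry) and ±10%
  (rests) keeps lift and trial durations inside one standard deviation of
  the observed scale (2.52 ± 0.56 s and 7.74 ± 1.09 s).

What the generator does *not* emulate — and hence what passing tests do not
show about real recordings: sensor drift and soft-tissue artifact (the noise
is white, not autocorrelated), anthropometric diversity beyond a global size
multiplier, within-participant movement variability and fatigue, hesitations
and secondary movements (except the explicit `false_start` mode), grasp
offsets between hands and object, and any kinetic quantities (forces,
moments, muscle activity). Classification accuracies on synthetic data are
upper bounds: the class-conditional kinematics are cleanly separated by
construction, which is what makes the pipeline's *correctness* testable, not
a claim about real-world accuracy. In particular, real weight classification
is near chance while the synthetic generator's deterministic speed scaling
makes it nearly perfect; the synthetic protocol validates the plumbing of
that subproblem, not its difficulty.

## Numerical notes and degenerate inputs

- `min_jerk` validates `t ∈ [0, T]`; endpoints are exact and endpoint
  velocities zero.
- The facing direction is undefined for exactly opposed foot headings, and
  the asymmetry angle for hands directly above the feet midpoint; both raise
  a degenerate-geometry error rather than returning an arbitrary angle.
- Standardization floors feature standard deviations at 1e-12 (constant
  features pass through unscaled rather than dividing by zero).
- Angle range branch cut: −180° maps to +180°.
- Validation reports at most five findings per check to keep reports readable
  on badly corrupted files.

## Known limitations

- Single-lift trials only; continuous streams and back-to-back lifts need a
  different (online) detector.
- Two-handed lifts only: every estimator uses the hands midpoint.
- The 28-joint registry is a stand-in; mapping real vendor exports onto it
  requires a column-name translation.
- NCA memory scales with n²·d; subsample before weighting very large tables.
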