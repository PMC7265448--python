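# Methods

This note documents the measurement model implemented by `dcvision`, the
parameter defaults and why they were chosen, what the synthetic generator
does and does not emulate, and the numerical conventions that make the
pipeline deterministic.

## The measurement model

A Defence Cascade test is a 30 s recording of a single pig following a
startling stimulus at a known onset time `t0`.  Every modality is reduced
to a *motion series* `m(t) ≥ 0` sampled at the modality's native rate,
and two quantities are extracted identically from any such series:

**Startle magnitude.**  The startle is a whole-body impulse lasting a few
hundred milliseconds.  Its magnitude is `max m(t)` over the half-open
frame window `[t0, t0 + round(0.7 s · rate))`, evaluated on valid frames
only, ties resolved to the earliest frame.  Windows are computed by
rounding once at the stated rate (140 frames at 200 Hz, 21 at 30 Hz,
280 at 400 Hz), so results are reproducible across modalities with
different clocks.  A series too short to contain the full window is
refused rather than silently truncated — a truncated window would bias
magnitudes downward invisibly.

**Freeze duration.**  A freeze is tense immobility.  A frame is frozen
when `m(t) < θ` (strict inequality; the boundary rule is arbitrary but
must be fixed and is declared here).  Frozen runs inside
`[t0, t0 + round(30 s · rate))` shorter than 0.4 s are discarded, the
rest are summed.  Two edge rules:

* a run truncated by the end of the record window still counts if its
  observed duration reaches 0.4 s (the observation simply ended during a
  freeze);
* an *invalid* frame (no measurement — e.g. no eligible tracked points,
  empty depth foreground, all markers occluded) breaks a run, because
  immobility cannot be asserted without a measurement.

**Threshold calibration.**  θ is empirical.  It is chosen against
observer-coded ground-truth durations by k-fold cross-validation
(default 10 folds × 10 repetitions, shuffled fold assignment seeded from
`AnalysisConfig.rng_seed`).  Per fold, 200 log-spaced candidates spanning
the pooled positive value range are evaluated on the training 90 %, the
candidate minimising the mean absolute error between detected and
observer durations is selected, and the error of that candidate on the
held-out 10 % is recorded.  The final threshold is the mean of the
fold selections, reported with the per-fold spread.

Two choices here were genuinely open and deserve comment:

* *Calibration loss.*  Mean absolute duration error, not occurrence
  accuracy: the calibration target is a duration, and MAE is robust to
  the many zero-duration tests.
* *Tie-break on the loss plateau.*  The training error is typically flat
  over a band of thresholds separating immobility from baseline motion.
  The **median** candidate of the minimising set is selected, placing θ
  mid-band.  An earlier revision took the lowest minimiser; that parks θ
  at the band edge, where per-test offsets in the immobility floor (for
  the load platform, the error in the baseline weight estimate) can
  split a long freeze into fragments — and a fragment shorter than 0.4 s
  is then discarded entirely, a large error from a tiny perturbation.
  Mid-band selection maximises the margin in both directions.

## Modality reductions

**KLT (overhead video).**  Shi–Tomasi corners (scikit-image) are tracked
frame-to-frame by an iterative pyramidal Lucas–Kanade solver (3 levels,
15×15 windows, bilinear sub-pixel sampling; points are dropped on
ill-conditioned gradient structure, window escape, or a large
post-convergence residual).  The tracker holds up to 150 points; large
losses trigger immediate re-detection (excluding a 5 px radius around
surviving tracks), small shortfalls are retried on a 5-frame cadence.
Per frame, every point valid over 2 (speed) or 3 (acceleration)
consecutive frames contributes its difference magnitude; the frame
statistic is the **mean of the 50 largest** (the single-point maximum is
available via `aggregate="max"` for sensitivity analysis).  The mean was
chosen over the raw 50th-fastest or the maximum because it is robust to
single-point tracker glitches while still weighting the moving animal
over the static background.  The 3-consecutive-frame eligibility rule is
applied to acceleration; speed requires only the 2 frames a first
difference needs.

**Load platform.**  `m(t) = |F(t) − W| / W` in gravities, with `W` the
mean summed force over the 1.0 s immediately before `t0` (recent enough
to track posture; configurable).  The absolute value makes the startle
statistic literally the peak absolute acceleration, and freezes are
detected on the same absolute series.  The measure is invariant to a
common rescaling of the four channels, so raw voltages work as well as
calibrated forces.

**Depth camera.**  Foreground = pixels deviating more than 30 mm from a
static background model (e.g. median of empty-pen frames); centroid
height = unweighted mean of (background − depth) over the mask.  Frames
with an empty mask are invalid; more than 10 % of them is a data-quality
error.  Heights are differenced into mm/frame and mm/frame² via the same
kinematic differencing used everywhere.

**Marker kinematics.**  Only vertical (z) motion is used.  Occlusion
gaps of at most 2 frames are linearly interpolated (routine reflective
marker dropout); longer gaps invalidate the dependent difference frames.
Per frame the series is the mean over the markers valid at that frame.
Marker records are 15 s and therefore excluded from freeze estimation —
`freeze_from_modality` refuses marker series by construction.  Native
200 Hz marker data are decimated to 30 Hz by nearest-frame selection on
a common clock.

## Observer ground truth

The 0–4 startle score is the rank of the strongest reaction present
(flee 4; jump-and-fall, jump-away 3; jump-on-spot, spin-to-face 2;
side-step, head-up, head-turn, muscle-ripple, ear-prick 1).  Sniffing or
approaching the stimulus and the outcome behaviours (flee is scored,
slowly-leave and return-to-normal are not) contribute nothing.  Observer
freeze duration sums coded freeze events of at least 0.4 s; an exactly
0.4 s freeze is retained (only strictly shorter events are
re-classified).  The scoring function is monotone (adding an event never
lowers the score) and order-independent; the test suite verifies both
and enumerates all 2^10 subsets of scored codes.

## Validation statistics

Spearman ρ uses mid-ranks — with a 5-level observer score, ties are the
norm, not the exception.  Freeze occurrence is `duration > 0` exactly
(durations are already minimum-run filtered upstream).  Sensitivity,
specificity, PPV and NPV are reported with zero-denominator cases
flagged undefined (NaN) rather than coerced to 0 or 1.  No p-values are
attached to the correlations: tests are nested within sessions within
pigs, so independence assumptions fail; modelling that hierarchy is
out of scope, and ρ with its n is reported instead.

## The synthetic generator

Real recordings of this protocol are not publicly deposited, so the
generator is the package's test bed.  A `Scenario` scripts one test: a
textured ellipse over a textured floor wanders with mean-reverting
Gaussian positional jitter (`baseline_motion_sd`, default 0.3 px/frame),
performs a one-frame displacement impulse of `startle_amplitude` px at
`t0`, and holds still (jitter × 0.02) during scripted freeze intervals.
The same script drives the load channels (weight + 50 ms exponential
impulse transient + noise, default sd 0.02 g), the depth sequence (a
height field with a vertical hop, sensor noise default 1 mm/pixel), the
markers, and an observer record that re-scores exactly to the intended
score and duration.  Fixed conversion constants (0.05 g and 3 mm of
vertical motion per pixel of scripted amplitude) keep the modal
amplitudes rank-consistent.  Default video is 160×160 at 50 Hz — the
metric definitions depend on rate only through the window arithmetic,
not on resolution, and 200 Hz rendering is a parameter away.  All
streams derive from a single seed; identical scenarios are bit-identical.

What the generator does **not** emulate: pig shape and gait, habituation
across repeated tests, stimulus-type and orientation effects, lens
distortion, rolling shutter, depth shadows and specular dropout, load
cross-talk.  Passing recovery tests therefore demonstrate that the
*computations* are correct and that the pipeline recovers scripted
kinematics under controllable noise — they do not certify performance
on real animals.

## Test corpora and problem sizes

The validation suite uses desk-scale corpora chosen to keep the full run
in minutes: 30-test graded-amplitude corpora (video at 160×160/50 Hz
with 2 s records for startle rank agreement), a 30-test load+depth
freeze-recovery corpus with freezes of 0.4–10 s and half no-freeze
tests, and 10 s end-to-end clips.  The freeze-recovery corpus is
constructed *separable* — brisk wander (`baseline_motion_sd` = 1.0) and
modest depth sensor noise (0.5 mm) — because the ±2-frame recovery claim
is a property of the detector under separation, not of arbitrary noise:
with iid sensor noise, a run boundary extends k frames with probability
≈ P(|noise| < θ)^k, so no threshold detector achieves frame-exact
boundaries when the immobility floor and the baseline motion
distribution overlap.  For the same reason the ±2-frame duration check
is made on the 30 Hz depth series (66 ms tolerance), while the 400 Hz
load series — where two frames are 5 ms — is held to exact occurrence
agreement (no false positives or negatives) rather than to a 5 ms
duration tolerance.

## Known limitations

* The LK tracker assumes brightness constancy and small inter-frame
  motion per pyramid level; violent multi-body motion or lighting
  transients will shed points (they are replaced, at the cost of brief
  eligibility gaps in the acceleration series).
* No physical-unit conversion between modalities is attempted; series
  are compared through ranks and thresholds in native units.
* The 4-point pen-corner homography accepted in video metadata is a
  planar correction only; no lens model is fitted.
* Freeze onset before the stimulus is not evaluated; only the
  post-stimulus window is scanned.
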