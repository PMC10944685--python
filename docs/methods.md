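# Methods

## Recording model and coordinate conventions

A recording is a gapless sequence of 25-keypoint pose frames
(BODY_25 layout: nose, neck, midhip, bilateral shoulder/elbow/wrist/
hip/knee/ankle/eye/ear/big-toe/small-toe/heel) at 30 fps in pixel
coordinates, origin top-left, y downward. A confidence of 0 marks a
missing detection. Frames are 0-indexed; all intervals are half-open
`[start, end)`.

The walking protocol is an L-shaped course: the subject sits, stands,
walks 2 m (lateral camera view), turns 90° right at the first floor
marker, walks 2 m toward the camera (frontal view) and stops at the
second marker.

## Calibration

The base scale is `marker_distance_cm / ‖marker1_px − marker2_px‖`
(default 200 cm). Each straight segment may carry its own marker pair;
otherwise both share the base scale. No homography or lens model is
attempted: within a straight segment a single scalar cm/px is the
operative assumption, and the synthetic renderer is built so that this
assumption is exact in the large (see below). Coincident markers raise a
degenerate-calibration error.

## Misdetection correction

Frame-independent pose estimation occasionally swaps or misplaces a
foot for a single frame. A frame is **abnormal** when any monitored
keypoint (the 12 lower-limb points: bilateral hip, knee, ankle, big toe,
small toe, heel) moves more than +50 px in the positive direction or
more than 35 px in the negative direction along either image axis,
measured against that keypoint's **last valid location** — its position
in the most recent frame that was neither abnormal nor missing.
Comparing to the raw previous frame would flag the return jump after
every single-frame spike as a second anomaly; the last-valid reference
flags exactly the corrupted frames. The asymmetry of the thresholds is
taken as given (the positive image direction is the dominant walking
direction in this camera setup).

In every abnormal frame all 12 lower-limb keypoints are deleted and
re-filled per keypoint per axis by a cubic spline through up to 4 valid
frames on each side of the abnormal run (a run touching the series
boundary is extended with the nearest valid value instead of
extrapolating). Missing detections (confidence 0) of monitored keypoints
are filled the same way. Frames and keypoints outside the abnormal set
are returned bit-identical, and re-detection on corrected output is
empty for all fixtures used (idempotence).

## Walk-phase segmentation

All phase logic runs on the pelvis (midhip) trajectory, with three
smoothing scales chosen for the artefact each signal must reject:

* **Stand-up** — first sustained (≥ 0.2 s) upward vertical speed above
  10 cm/s on a 0.3 s-smoothed trajectory, with boundaries extended to
  the 2 cm/s crossings.
* **Stop** — last frame whose 5-frame-smoothed speed exceeds half the
  75th-percentile walking speed; the half-height crossing of a smoothed
  step is an unbiased edge estimate.
* **Cornering** — the travel heading is computed from the velocity
  after a zero-phase 4th-order Butterworth low-pass at 0.8 Hz (the
  step-frequency pelvis bob is a ~2 Hz vertical oscillation whose
  velocity can rival the forward speed of a very slow walker, and would
  otherwise masquerade as heading rotation). The **unit** direction
  vectors — not the velocities — are then smoothed with a double 1 s
  moving average (triangular kernel), so slow turn frames are not
  outvoted by fast straight frames inside the kernel. The turn is the
  longest ≥ 0.3 s run of rotation rate above 6°/s, refined to the
  half-height crossings of the rotation-rate plateau.

Segment 1 spans stand-up end to turn start; segment 2 spans turn end to
the stop frame. A missing phase raises an error naming it. On the
synthetic walker all boundaries are recovered within ±5 frames across
the four frailty presets.

## Gait events and the named parameters

Heel strikes and toe-offs use relative-excursion extrema (the
pose/marker-data standard): a heel strike is the peak of the heel's
forward excursion relative to the pelvis (equivalently the heel's
forward-velocity minimum), a toe-off the peak of the pelvis's excursion
relative to the big toe. Excursions are the projection of the
(lightly 3-frame-smoothed) relative displacement onto the instantaneous
travel direction, detrended at the stride scale — the constant
anatomical heel-below-pelvis offset would otherwise rotate into the
travel direction during the turn and swamp the stride oscillation.
Events are detected over the whole walking region (stand-up end to
stop): strides legitimately span the turn. Peaks are accepted at ≥ 30 %
of the signal's 5–95 % range; fewer than two heel strikes on a side is
an error.

Named parameters:

* `total_gait_time_s` — stand-up onset to stop frame.
* `cornering_time_s` — length of the turn interval.
* `gait_speed_cm_s` — calibrated path length of the smoothed midhip over
  the two straight segments divided by their duration.
* `gait_width_cm` — median forward heel-to-heel distance at heel
  strikes, i.e. step length. (The mediolateral base of support is not
  resolvable in a lateral view, and published per-frailty values of
  20–47 cm that decrease with frailty are step lengths.)
* `stance_phase_pct` — mean of (toe-off − strike)/(next strike − strike)
  per stride, × 100.
* `ankle_swing_speed_cm_s` — mean calibrated ankle speed during the same
  side's swing windows (toe-off → next strike);
  `wrist_swing_speed_cm_s` the same for the wrist contralateral to the
  swinging leg (the arm swings with the opposite leg).
* momenta — effective limb mass × swing speed: whole-limb mass fractions
  from standard anthropometry, lower limb 0.161 and upper limb 0.050 of
  body mass (configurable). These defaults land on published magnitudes
  (e.g. ~17 kg·m/s at ~2.1 m/s for a ~50 kg patient) and are this
  package's choice, not a value quoted from elsewhere.

## The 128-feature registry

The model consumes a fixed, versioned, ordered vector: the 9 named
parameters, 114 per-keypoint statistics, 5 clinical covariates
(123 video + 5 clinical). The statistics are deterministic by
construction: 19 body keypoints (the schema minus the five head
landmarks, which duplicate the neck for gait purposes, and the midhip,
already summarised by the named parameters) × 2 straight segments ×
3 statistics (mean speed, max speed, vertical excursion range) = 114.
Any change bumps `REGISTRY_VERSION`, which trained models record.

## The rating model

A LightGBM regressor with the extra-trees variant enabled. Development
loop: (1) a preliminary model on all 128 features yields exact tree-path
SHAP attributions (additivity holds to 1e−6 per sample); the mean |SHAP|
ranks features; (2) an 80/20 split stratified by label, then a seeded
random search (default 50 rounds) over a top-k cutoff on the ranking
(log-uniform, k ≥ 5) and hyper-parameters (leaves 7–63, learning rate
0.02–0.2 log, 100–500 trees, min-child 3–20, feature/bagging fractions
0.6–1), scored by 5-fold CV RMSE on the training part; the best round is
refit on the full training part. Internal reliability uses a 90/10 split
and 10-fold CV with per-fold kappa/ICC. Random search (rather than a
TPE-style sampler) is the default because it is reproducible and
sufficient at this scale. One seed drives every random choice;
LightGBM runs in deterministic single-thread mode.

**Band-centre target.** The regression target is `label + 0.5`, the
centre of the labelled frailty band. An L2 regression on the raw integer
label centres its predictions on the bin edges, where the floor that
maps FL to CFS flips a coin; band-centre training makes flooring a
nearest-band decision and produces per-class FL medians that sit
mid-bin, the pattern observed in practice. The output contract is
unchanged: FL is clipped to [3.0, 6.99] (the cohort definition excludes
CFS < 3 and > 6) and predicted CFS = ⌊FL⌋ with lower-closed bins.
An optional monotone constraint (e.g. FL non-decreasing in total gait
time) can be enabled per feature.

## Agreement statistics

Weighted kappa uses disagreement weights ((i−j)/(k−1))² (quadratic,
default) or |i−j|/(k−1) (linear); κ_w = 1 − Σw·p / Σw·e with p the joint
proportion table and e the product of its marginals. ICC is ICC(2,1):
two-way random effects, absolute agreement, single measurement, from the
two-way ANOVA mean squares. Quadratic weighting is the default because
it is asymptotically equivalent to ICC(2,1) — the reason the two
statistics typically agree to two or three decimals on the same rating
pairs (verified as a property: |κ_q − ICC| < 0.02 on large simulated
rating sets). Confidence intervals are percentile bootstrap (default
1000 resamples of subjects with pairs intact; degenerate resamples
skipped, > 50 % degenerate is an error). Interpretation bands: ≤ 0.20
none, 0.21–0.39 minimal, 0.40–0.59 weak, 0.60–0.79 moderate, 0.80–0.90
strong, > 0.90 almost perfect; values are rounded half-up to two
decimals first, so 0.905 is "almost perfect" while the printed edge
0.90 stays "strong".

## Risk score and survival models

The MAGGIC integer score is embedded as a versioned constant table:
EF bands (< 20 → 7 … ≥ 40 → 0), age per decade with an EF interaction
(up to 10/13/15 points at ≥ 80 years for EF < 30 / 30–39 / ≥ 40),
SBP per 10 mmHg with the same interaction, BMI (< 15 → 6 … ≥ 30 → 0),
creatinine banded to 350 µmol/L (top band 8), NYHA (0/2/6/8), and
binary points for male sex (1), smoking (1), diabetes (3), COPD (2),
HF duration > 18 months (2), no ACEi/ARB (1), no beta-blocker (3).
The interactions make greedy per-component maximisation unsafe, so the
extreme total is found by exhaustive enumeration over all band
combinations (binaries enumerated per covariate, being additive); the
maximum is 57. Out-of-range covariates are clamped to the table bounds
with a warning; a missing covariate is an error naming it.

Cox models for all-cause death, exposure = predicted CFS (per category)
or FL (per 1.0): unadjusted; + age, sex; + MAGGIC total; + MAGGIC and
NT-pro BNP; + MAGGIC, NT-pro BNP and albumin. NT-pro BNP enters as the
natural log by default (it is heavily right-skewed; a flag restores the
raw scale). Ties use Efron's method; the proportional-hazards assumption
is tested on scaled Schoenfeld residuals and reported per model.

## The synthetic walker

A kinematic stick figure on the L-course, rendered directly in image
coordinates (no 3-D camera model). The course is two straights joined by
a quarter-circle arc of 50 cm radius traversed in the configured
cornering time, so the heading rotates smoothly. Feet alternate exact
stance plateaus (zero velocity at constant body speed) with swings that
advance one stride under a trapezoidal velocity profile (10 % ramps) —
the brisk terminal deceleration of a real swing, which keeps the
relative-excursion extremum within a frame of foot contact. Stance
fraction, cadence, stride length and speed are mutually consistent
(speed = step length × cadence). The pelvis bobs vertically (1 cm at
step frequency); arms swing contralaterally; a smooth 0.3 s gate starts
and stops the limb oscillation at the walking-window edges.

The frontal straight is rendered with a depth-dependent local scale
(±3 % linear variation) whose integral over the segment equals exactly
the marker-to-marker scale, so the single-scalar per-segment calibration
recovers segment distances exactly while local speeds still vary with
depth. Gaussian pixel jitter and single-frame foot misdetections are
injectable; a planted misdetection displaces one foot's six keypoints
coherently relative to their previous-frame position by the configured
magnitude, mimicking an estimator locking onto a wrong location, and
making the observed frame-to-frame displacement equal the configured
magnitude.

Presets for CFS 3–6 anchor gait speed (93.1/70.2/51.8/40.7 cm/s), step
length (47.3/35.2/26.5/20.0 cm), stance fraction (54.8/61.4/68.1/75.5 %)
and cornering time (2.63/3.73/5.13/7.93 s) to published
derivation-cohort medians; stand-up duration, lead-in and lead-out are
chosen per preset so recordings last 10–20 s. Total gait time is
emergent from the kinematics rather than anchored: on a fixed 4 m course
the published total-time and speed medians cannot both hold under
path-length kinematics, and speed, stance and cornering are the
quantities the feature extractor must recover. Parameter-recovery
tolerances met on clean walks: speed within 5 %, stance within 3 points,
total time within 5 %, phase boundaries within ±5 frames.

## The synthetic cohort

Per subject: a CFS level is drawn with prevalence 108:64:18:4 (the
derivation split over levels 3–6); a continuous frailty level is the
class plus a clipped N(0.45, 0.18) offset; the rated label adds
N(0, 0.1) observation noise before flooring (a small residual
inter-rater error left after consensus). The nine named gait parameters
are log-normal with median and sigma log-linearly interpolated between
the per-class anchors (medians and IQR-derived sigmas) at the per-class
FL medians (3.57/4.35/5.32/6.07), sharing a common latent factor
(ρ = 0.5, signed by each parameter's frail-ward direction). The 114
registry statistics are redundant noisy proxies: each follows a fixed
parent named parameter (lower-limb stats → ankle swing speed, arm stats
→ wrist swing speed, trunk stats → gait speed, vertical ranges → gait
width) times a fixed log-ratio and a 15 % log-normal noise. Walking-stick
use is logistic in FL (midpoint 4.8, scale 0.35, matching per-class
prevalences 0 %/8 %/61 %/100 %). Clinical covariates are drawn at
cohort-typical values for an elderly heart-failure population. Survival
is exponential with hazard 1.6e-4/day × exp(log 1.6 × (FL − 3)) and
independent uniform censoring over 180–750 days (~10–15 % events).

**What the generator does not emulate** — and therefore what passing
tests do not show about real data: soft-tissue and clothing artefacts,
view-dependent occlusion and left/right ambiguity beyond single-frame
spikes, lens distortion and true perspective, pathological gaits
(festination, ataxia, asymmetric stance), correlated multi-frame
tracking failures, and any real relationship between the clinical
covariates and gait beyond frailty itself. The cohort generator's
feature noise is log-normal and cross-sectionally exchangeable; real
cohort noise need not be either.

## Numerical choices and degenerate inputs

Trajectory smoothing is a centred 5-frame moving average before
velocity computation (30 fps pose jitter), with the deviations noted
above (3 frames for event excursions, Butterworth + 1 s triangular for
heading). Velocities are central differences × fps. Ties in the
multi-person reader break toward the lower person index. Weighted kappa
is undefined (error) when both raters put all mass in one category;
ICC is undefined at zero total variance; bootstrap skips degenerate
resamples. Series shorter than two frames yield an empty anomaly
report. The FL clip range [3.0, 6.99] keeps ⌊FL⌋ within the modelled
CFS 3–6.

## Problem sizes

Default study sizes used throughout the suite and examples: cohorts of
194 (derivation-sized) and 400 (end-to-end analogue: 194 train / 206
test), 50 search rounds with 5-fold CV, 1000 bootstrap resamples,
200 replicates for CI-coverage studies and 100 replicates per arm for
survival-recovery studies. These mirror the study design the package
emulates at sizes a workstation handles in minutes.

## Known limitations

The per-segment scalar calibration ignores within-segment depth change;
the frontal-segment speed profile is therefore locally distorted even
though segment distances are exact. The 114-statistic registry is this
package's deterministic completion of a feature inventory whose full
original listing is not public; it is versioned so models declare what
they were trained on. Gait width is step length, not base of support.
The momentum mass fractions are anthropometric defaults, not fitted
constants. Agreement statistics support exactly two raters.
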