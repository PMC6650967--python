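# Methods

This note documents the models, the numerical choices, and what the
synthetic data do and do not establish.

## Signal model and conditioning

Inputs are the foot-instep IMU's sagittal angular velocity `Gy` (deg/s)
and vertical linear acceleration `Ay` (m/s², gravity-removed), sampled at
100 Hz, and a four-channel FSR insole (heel, 1st metatarsal, 5th
metatarsal, hallux) sampled at 200 Hz.  Conditioning applies a running
median (default window 5 samples ≈ 50 ms; removes isolated outliers
without smearing crests) followed by a second-order low-pass Butterworth
at 17 Hz (accelerometer) / 15 Hz (gyroscope).  The Butterworth is applied
**zero-phase** (forward–backward): all analyses here are offline, and a
causal filter's group delay (≈ 10–15 ms at these cutoffs) would bias every
timing-error estimate; the cost is that the effective magnitude response
is the squared second-order response, which the tests' analytic oracle
accounts for.  Filter and derivative edges use boundary replication so no
spurious onset features appear at trial start.  For sample-wise scoring
against the reference, IMU-derived quantities are linearly interpolated
from 100 to 200 Hz.

## FSR reference labeling

Each phase corresponds to a binary activation pattern: HS = heel only,
FF = both metatarsals (heel/toe participation configurable), HO = toe with
heel off (1st metatarsal optionally required), SP = all off.  Channels are
binarized at 50 % of their trial maximum by default (hardware-calibrated
amplification plays this role on real insoles) with optional debouncing.
Patterns are evaluated most-specific-first (SP, HS, HO, FF) so that the
loaded forefoot with the heel off is read as heel-off rather than flat
foot.  Samples matching no pattern — double-support overlaps, sensor
chatter — hold the previous label, which keeps the output inside the
four-phase vocabulary; the per-subject pattern relaxations exist precisely
to absorb such cases, and the default relaxation (heel/toe ignored for FF,
mt1 ignored for HO) is the patient-safe choice.

## Threshold-based detector

Each signal has an independent feature scanner with seven feature kinds:
crossed-high/low (level beyond `d_high`/`d_low`), crest/trough-middle
(level beyond `d_crest`/`d_trough`), crest/trough (completion after the
signal re-crosses the threshold and `t_crest`/`t_trough` has elapsed), and
neutral (continuous residence in `[d_neutral_min, d_neutral_max]` for
`t_neutral`).  Level conditions are evaluated sequentially per sample,
first match wins, and every save is gated by a 150 ms refractory from the
previous save on that signal (crest/trough completions and neutral use
their own time constants instead).  Two structural consequences follow:

* crest-middle can only be saved while the signal sits in
  `(d_crest, d_high]`, so each signal's `d_crest` must lie below its
  `d_high`;
* pending extractor state (an unfinished crest, a running neutral
  residence) survives phase transitions — only the FSM's accumulated
  feature lists are cleared — so a crest that completes just after a
  transition is credited to the new phase, which the HS→FF rule depends
  on (the swing crest of the gyroscope completes right after HS onset).

The four transition rules consume ordered subsequences of the feature
lists (SP→HS: accel crest, trough, crossed-high with the current sample
above `d_crest`, gyro trough then crossed-high; HS→FF: saved accel crest
with the current sample below `d_trough`, gyro crest; FF→HO: accel neutral
residence ≥ `t_neutral` with gyro neutral then crossed-high; HO→SP:
current accel above `d_high` with gyro crest).  The unnamed threshold in
the HO→SP acceleration condition is taken to be `d_high` and is
configurable.  The initial phase defaults to SP: trials begin at steady
treadmill speed and SP has the unambiguous all-off insole signature.

Thresholds are data-dependent and never published for this class of
detector; defaults here are expressed relative to the simulator's waveform
amplitudes (e.g. gyro `d_crest` at 150 deg/s ≈ 38 % of the swing crest,
`d_high` at 250 deg/s ≈ 62 %), and `calibrate_thresholds` reproduces the
practical procedure: exhaustive grid search accepting configurations that
detect the known step count of a level-ground trial, tie-broken by the
largest worst-case margin between thresholds and signal extrema (the most
noise-robust of the equivalent configurations).

Timing interlocks are the detector's real constraint: a full stride must
accommodate ~14 saved features across the two signals, with most pairs
separated by 150 ms.  At stride durations under roughly one second the
chain no longer fits, which is consistent with this detector family's
known degradation at faster walking speeds; the simulator's healthy
default (below) therefore sits at the slow end of the healthy range.

## Left-right HMM

λ = (A, B, π) with four states in the cyclic phase order.  A starts at
0.9/0.1 (diagonal/successor, the SP row wrapping to HS), π is uniform, and
each state emits `o_t = (ω_t, ω̇_t)` — angular velocity and its
first-order finite difference — under a 3-component bivariate Gaussian
mixture, the standard flexibility/parameter-count trade-off for foot
gyroscope data.  Initialization is supervised: per-state mixtures are
fitted by EM (k-means++ start, seed-controlled) to the FSR-labeled feature
subsets; a state with fewer than 3 labeled samples is an error.

Baum–Welch re-estimates A, π and the mixtures over pooled sequences with
scaled forward/backward passes (per-step max-shifted emissions, so extreme
observations cannot underflow).  Numerical choices:

* convergence at relative log-likelihood improvement < 1e-4 or 100
  iterations;
* a diagonal covariance floor of 1e-6 × the pooled per-dimension variance
  each M-step — 3-component mixtures on small per-phase datasets collapse
  otherwise;
* structural zeros of A are invariant under EM (their expected counts are
  identically zero), so the left-right topology cannot be lost; a
  `update_transitions=False` flag freezes A at the prior entirely;
* features are fed raw (deg/s, deg/s²); optional z-scoring is deliberately
  absent since the Gaussian mixtures absorb scale;
* Viterbi decodes in log space, ties toward the lower state index; the
  trained π is used, and because the cycle closes (a₄₁ > 0) the chain is
  ergodic over strides and the initial state matters little on multi-
  stride sequences.

**Training regimes.**  SST (subject-specific): leave-one-trial-out over a
subject's three trials, initialization seed shared across folds so that
identical inputs give identical models.  SPT (standardized parameters):
for a healthy target, pool the first two trials of every other healthy
subject; for a patient target, build an ensemble-average stride — each
healthy stride is time-normalized per phase (10/35/26/30 points for
HS/FF/HO/SP, 101 per stride), averaged across strides and subjects per
normalized index, the derivative feature re-derived from the averaged
velocity, and the model trained on that averaged dataset (repeated three
times so transition statistics exist, at the effective rate implied by
the mean stride duration).  The averaging protocol for the patient branch
is one defensible reading of "train on averaged healthy angular
velocities"; it is isolated in `train_spt` and easy to swap.

## Evaluation indices

* **Timing errors**: per phase, greedy nearest-neighbor one-to-one
  matching of predicted to reference onsets within half a mean stride
  (prevents one predicted onset absorbing several reference events);
  error = t_pred − t_ref in ms, negative = anticipation.
* **Tolerance-windowed rates**: the 60 ms window is ±30 ms (≈ ±6 samples
  at 200 Hz) around each reference sample.  A reference sample of phase p
  is a true positive if any prediction in its window carries p; a non-p
  reference sample is a true negative unless the entire window is
  predicted p.  This operationalization makes a constant single-phase
  prediction on four equal phases score exactly 25 % sensitivity and 75 %
  specificity — the chance floor of the metric — and reduces to exact
  per-sample agreement at zero tolerance.  The exact false-positive
  accounting inside the window is under-determined in the source
  literature (texts conflate false negatives and false positives in the
  specificity denominator); the reading above is one consistent choice,
  isolated inside `sample_metrics`.
* **Goodness index**: G = √((1−TPR)² + (1−TNR)²); macro G is the G of the
  phase-averaged rates (per-phase G is also reported).  Bands: optimum
  ≤ 0.25, good < 0.7, random ≈ 0.7 (√½), bad above.
* **Confusion matrix / accuracy**: sample-wise *without* the tolerance
  window, row-normalized percent — it describes raw confusion while the
  windowed rates describe event-level detection; both are reported.
* **MT / CoV**: strides run HS onset to HS onset; incomplete edge strides
  are dropped; std uses n−1 (stride counts per trial are small);
  CoV = 100·std/MT.
* **ICC(A,1)**: absolute-agreement single-measurement two-way ICC from
  ANOVA mean squares, (MSR − MSE)/(MSR + (k−1)MSE + (k/n)(MSC − MSE)),
  with the usual reliability bands; a zero-variance matrix returns 1 with
  the degenerate-case caveat.

## Synthetic gait generator

The generator composes strides from piecewise-linear templates anchored
per phase — swing crest (+400 deg/s), foot-slap trough (−220 deg/s),
flat-foot plateau, heel-off bump (+310 deg/s) and toe-off trough on the
gyroscope; impact transient (+10 m/s²), post-impact oscillation, flat-foot
dip, stance neutral band and push-off rise on the accelerometer — with the
FSR channels following the canonical activation sequence.  Anchors live in
phase-local coordinates, so stride-duration jitter (lognormal, CV 3 % by
default, with per-phase fraction jitter at half that spread) warps the
waveform consistently with the ground-truth boundaries.  White noise is
added at the IMU (8 deg/s gyro, 0.3 m/s² accel by default — a
mid-grade MEMS noise floor relative to the 400 deg/s swing amplitude).

Study conditions: phase fractions 0.10/0.35/0.25/0.30 (HS shortest, FF
longest, matching the event distribution of normal gait); cadence derived
from treadmill speed through a fixed nominal stride length (0.7 m healthy,
0.5 m at full hemiparetic severity).  The healthy default speed is
0.639 m/s — the slow end of the healthy treadmill range, chosen once
because it is the regime where all waveform features per stride clear the
threshold detector's 150 ms refractory (see above), and because it
overlaps the speeds attainable by hemiparetic walkers, making
healthy/pathological comparisons meaningful.  The hemiparetic preset
interpolates with severity ∈ [0,1]: speed down to 0.278 m/s, stride CV up
to 10 %, heel-strike impact and foot-slap trough attenuated by up to 45 %.
Each trial opens with the swing portion of a lead-in stride so detectors
observe a complete pre-HS feature sequence before the first labeled heel
strike.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: biomechanical kinematics (templates are bump
compositions, not joint dynamics), soft-tissue and mounting artifacts,
sensor drift and axis misalignment, FSR analog dynamics (channels switch
ideally apart from the configurable double-support overlap), asymmetric
left/right impairment, and turning or non-steady walking.  Recovery
results on simulated trials demonstrate the correctness of the estimation
machinery at realistic signal-to-noise, not clinical performance.

## Problem sizes

Default experiments use 10–12 strides per trial (≈ 11–13 s at the healthy
cadence), three trials per subject and four simulated subjects for the
inter-subject regime; the oracle-equivalence suites enumerate all 4^L
paths for L ≤ 6 over 100 seeded random models.  These sizes keep every
experiment's sampling error far from the decision boundaries being tested
(goodness bands, 60 ms timing bounds) while the full suite runs in well
under a minute of compute.
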