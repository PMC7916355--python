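# Methods

## Problem

A toothbrush instrumented with a nine-axis IMU (3-axis accelerometer in g,
gyroscope in deg/s, magnetometer in µT) streams motion data while the user
brushes. The task is to recognize, frame by frame, which of 15 brushing
regions (outer/inner/chewing surfaces × left/right/front × upper/lower,
following the Bass technique's region breakdown) the brush is working on,
and from the resulting label stream to score brushing completeness against
a prescribed schedule. The discriminating signal is the brush *attitude*:
each region is brushed with a characteristic orientation, so the Euler
angles (pitch, roll, yaw) separate the regions.

## Feature extraction

At rest the accelerometer measures the gravity direction, giving the tilt
angles

    pitch = asin(ay),        roll = -asin(ax / cos(pitch)),

with normalized accelerometer components. The roll formula is the standard
accelerometer-tilt form: the division by cos(pitch) normalizes the x-axis
reading by the tilt of the measurement plane. Its arcsine has principal
range [-90°, 90°]; `attitude_from_accel` extends roll recovery to
(-180°, 180°] via `atan2(-ax, az)`, using the sign of az to disambiguate.
Within ±0.1° of pitch ±90° the formula degenerates (gimbal lock) and a
`GimbalLockError` directs callers to the fused orientation.

During motion, accelerometer tilt alone is noisy and yaw is unobservable,
so a complementary filter fuses the three sensors: the gyro propagates the
previous attitude through the Euler kinematic map (inverted per sample;
near gimbal lock the propagation step is skipped and the accelerometer
correction takes over), and the accel/magnetometer measurements correct the
prediction with weight `1 - alpha` (default alpha = 0.98). Yaw comes from
the tilt-compensated magnetometer only — gravity carries no heading
information.

Upstream of fusion, each of the nine channels is smoothed by a scalar
constant-position Kalman filter (state x_k = x_{k-1} + w, observation
z_k = x_k + v). The defaults (process variance 0.5, measurement variance
0.05, steady-state gain ≈ 0.92) deliberately smooth only lightly: brushing
dynamics are fast (2 Hz strokes, rates above 100 deg/s), and a low-gain
filter corrupts exactly the gyro signal the fusion integrates. Holder
calibration estimates accel/gyro biases from an initial low-motion window,
with the holder's upright gravity (0, 0, 1) g as reference.

A rule table on (az, ax, roll, pitch) classifies coarse brush *steering*
(face-up / down / left / right). The four rules overlap and leave gaps, so
they are applied with fixed precedence UP, DOWN, LEFT, RIGHT (first match
wins, else UNKNOWN), making the classifier total and deterministic.

The classifier feature vector is (pitch, roll, yaw) per frame; an extended
set appends the calibrated accelerometer axes. Features are z-scored with
training-set statistics (variance floor 1e-8; constant columns are flagged
and map to zero).

## Classifier

The core model is a probabilistic neural network (Specht's Gaussian-Parzen
form): training stores the standardized feature vectors; the posterior is

    P_c(x) ∝ prior_c · (1/n_c) · Σ_j exp(-||x - x_cj||² / (2 σ_c²)),

with per-class smoothing widths σ_c initialized to the mean within-class
nearest-neighbor distance and refined by tuning. Kernel sums are
accumulated in the log domain (logsumexp) so posteriors stay exact for
large pattern counts; a query where every kernel underflows to -inf falls
back to the class priors. Ties in the argmax break to the lowest class
label. Because fitting is pattern storage, adding labeled data is O(new
patterns) — the property the personalization stage exploits.

## Recurrent memory unit

Streaming decisions are smoothed by a per-class accumulator. At step t
with raw posterior P(t), gain K > 0 and forgetting factor δ ∈ [0, 1):

    P*_i(t) = K · P_i(t)   if t ≠ 0, else 0
    winner i* = argmax_i P_i(t)   (raw posterior; lowest index on ties):
        P_update,i*(t) = (1 - δ) · (P_update,i*(t-1) + P*_i*(t))
    losers:
        P_update,i(t)  = δ · (P_update,i(t-1) + P*_i(t))

The emitted label is the argmax of the accumulator. The equations are
implemented verbatim, including the loser branch's multiplication by δ
(strong suppression for small δ) and the t = 0 branch that zeroes every
accumulator; while the accumulator is identically zero the raw posterior
argmax is emitted, which makes a single-frame stream equal to the raw
classifier. The excitation applied to the accumulator is the identity;
sum-normalized snapshots are available for reporting but never used for
decisions. Accumulators are non-negative and bounded by (1-δ)·K·sup P/δ
(geometric series), which the tests check over 10,000-step random streams.

A consequence of the literal equations worth knowing: at steady state the
winner's accumulator is ≈ (1-δ)K·p̄/δ, and an isolated contrary frame flips
the decision iff its posterior exceeds roughly the running winner's mean
posterior (margin (1-δ)K(p̄ - p_spike) + δK p_true). The memory therefore
absorbs transients whose evidence is weaker than the accumulated run, but
a single overwhelming frame (posterior near 1 against an unsaturated run)
still wins. Larger δ lengthens the memory; δ is exactly what the tuner
adjusts under transient noise.

## Hyperparameter tuning

Global-best PSO over the triple (log10 σ-scale, δ, K) with bounds
[-1, 1] × [0, 0.9] × [0.1, 10]:

    v ← w·v + c1·r1·(pbest - x) + c2·r2·(gbest - x),  x ← clip(x + v)

with w = 0.30, c1 = c2 = 2.0, 50 particles, 100 iterations by default,
velocity clamped at 0.5 of each dimension's span, boundary handling by
clipping, fully reproducible from the seed. (Some sources label the pbest
term "social" and the gbest term "cognitive"; the implementation uses the
conventional roles — with c1 = c2 the numerics are identical.) Fitness is
frame-level accuracy of the memory-smoothed classifier on held-out
validation sessions, so σ-scale, δ and K are traded off on data with the
stream structure deployment will see. The untuned default triple
(σ-scale 1, δ = 0.2, K = 1) is injected as one initial particle, so tuning
can never end below the default on the validation set. Tests and the
acceptance script run the swarm at 8 particles × 6 iterations — the search
space is 3-dimensional and smooth, and this size already recovers the
validation optimum on the desk-scale benchmark.

## Personalization (model migration)

A model trained on source users generalizes imperfectly because each user
holds the brush with a systematic attitude offset. Personalization:
(1) append the target user's labeled calibration patterns (labels come from
the scripted calibration protocol — the user brushes the prescribed region
sequence); (2) optionally cap retained source patterns per class (a seeded
subsample; cap 0 degenerates to a target-only model); (3) re-tune
(σ-scale, δ, K) on a held-out split of the target sessions. The source
model is never mutated. With no target data the source model is returned
unchanged, and for a target whose distribution matches the source the
change in accuracy is bounded (< 2 points median in the acceptance check).

## Evaluation

Per-class one-vs-rest counts feed accuracy, precision, recall and the
weighted F-measure F_a = (a²+1)PR / (a²(P+R)) (F1 at a = 1). Classes with
TP+FP = 0 have undefined precision, reported as 0 with a flag. Multi-class
summaries are macro- (default) and micro-averaged; for single-label
multi-class data micro-precision = micro-recall = accuracy, which the tests
assert as an identity. Brushing completion is per-region dwell time over
prescribed time × 100%, capped at 100% per region so over-brushing one
region cannot mask neglect of another (the uncapped ratio is also
reported); the default schedule splits the dentist-recommended two minutes
equally, 8 s per region. Frames labeled 0 (unlabeled / inter-region
transitions) are excluded from accuracy and accrue no dwell.

## Synthetic data generator

Real brushing recordings of this kind are confidential, so the generator
emulates their statistical structure; all numeric profiles are package constants
constructed from the qualitative Bass postures, not measured data.

* **Region profiles.** 15 mean attitudes; outer surfaces use a ≈45° tilt
  toward the gum line (roll 40°; 40° rather than the nominal 45° so the
  noise-free prototype sits inside the face-up steering band rather than on
  its open boundary), inner surfaces are steeper with the brush inside the
  arch, chewing surfaces are face-up (roll 0°) or face-down (roll 150°).
  Upper/lower jaws flip the roll sign; left/right/front positions spread
  yaw. Every pair of profiles is separated by ≥ 20° in at least one angle.
* **Kinematics.** True attitude = profile mean + per-user offset + 2 Hz /
  10° sinusoidal stroke on pitch (Bass strokes are short vertical sweeps)
  + AR(1) Gaussian noise with marginal σ = 5° and coefficient 0.9. The
  band limit reflects that hand tremor at 50 Hz is strongly correlated —
  white 5° frame-to-frame noise would imply angular rates of hundreds of
  deg/s, which no finite-bandwidth filter could follow. Between regions
  the attitude moves continuously over 0.2 s; those frames carry label 0
  (ground truth is neither region).
* **Sensors.** accel = R(pitch, roll)·(0,0,1) g, gyro = exact Euler-rate
  kinematics of the true attitude, mag = R_nb·(22, 0, 40) µT, plus white
  sensor noise (0.01 g, 1 deg/s, 0.5 µT). A noise-free session therefore
  round-trips through the feature extractor exactly (< 1e-6°), which is
  the generator's conformance test.
* **Transient condition.** For the memory-vs-raw comparison, single-frame
  "knock" disturbances hit one angle with probability 0.08/frame and
  σ = 45° — large enough that raw decisions actually flip, so the
  comparison is not vacuous.
* **Users and scale.** Per-user systematic offsets ~ N(0, 5°) per angle.
  The desk-scale benchmark is 5 users × 15 regions × (200 train / 50 val /
  100 test) frames per region at 50 Hz, one session per split per user,
  disjoint seeds per split; a full-scale flag switches to 2000 train /
  1000 test frames per region.

What passing on this generator does **not** show: robustness to real
accelerometer vibration spectra, magnetic disturbance indoors, soft-tissue
contact forces, non-stationary user habits within a session, or region
attitudes that differ from the constructed table. The generator's regions
are as separable as the qualitative Bass postures suggest; real inter-user
variation may be larger than the 5° offset model.

## Numerical and design choices

* Sampling rate default 50 Hz (configurable); all angle units degrees.
* Steering thresholds are applied to holder-calibrated accel.
* Log-domain kernel sums; distance blocks of 512 query rows bound memory.
* Variance floor 1e-8 in standardization; σ floor 1e-6.
* Tie-breaks everywhere to the lowest index/label, for determinism.
* Kalman defaults q = 0.5, r = 0.05 (see Feature extraction for why).
* Fusion alpha 0.98; magnetometer absent → yaw integrates gyro only.
* The attitude-only feature set is the default; gyro/accel appending is
  available but off, since the region signal is the attitude itself.
* Completion caps at 100% per region; raw ratio reported alongside.
* Model archives are JSON: patterns, widths, priors, standardization
  statistics, (δ, K), user tag, and the producing seed/config hash.

## Known limitations

* The memory recursion is implemented exactly as specified; its transient
  suppression is margin-limited (see above) and provides roughly 1–2
  frames of hysteresis at region changes rather than long-horizon
  smoothing.
* A pattern-storing PNN's size grows linearly with training data; the
  per-class cap is a blunt instrument, and no condensation/prototype
  learning is provided.
* Yaw depends entirely on the magnetometer reference; indoor magnetic
  distortion would degrade the left/right/front separation first.
* The arcsine roll formula cannot distinguish |roll| > 90°; all full-range
  paths go through the atan2 recovery.
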