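# Methods

This note documents the models and procedures implemented in `repanom`, the
assumptions behind them, the parameters that matter, and what the synthetic
benchmark does and does not demonstrate.

## Data model and assumptions

A session is a time-major array of nine kinematic feature channels at a
fixed frame rate (default 30 Hz): two unit-vector channels (upper-arm and
forearm pointing direction, expressed in the per-frame upper-torso frame)
and seven scalars (torso frontal flexion, turn, lateral flexion; forearm
pronation; wrist x/y/z in a static *core* frame anchored at the first
frame).  The central assumption is quasi-periodicity: the movement is a
repetition of one cycle, so every channel is approximately a function of a
latent phase φ ∈ [0, 2π), traversed at a varying (but non-negative) rate.
Pauses are phase-rate ≈ 0 stretches of recorded data, not gaps; missing
samples must be interpolated before entry.

## AZEQ projection

Directional data live on the unit sphere, where linear statistics (PCA,
averaging) are invalid.  Each spherical channel is rotated by the minimal
rotation taking its training-mean direction to +Z (roll about Z fixed to
zero for determinism), then mapped by the azimuthal equidistant projection
p = θ(cos α, sin α) with θ the polar angle and α the azimuth.  The map is a
bijection away from the south pole, preserves angular distance from the
pole, and places its tear antipodal to the data mean.  Numerics: θ is
computed as `atan2(hypot(wx, wy), wz)` (full precision near the poles, where
`arccos(wz)` loses ~8 digits); unprojection clamps ‖p‖ to π − 1e−9 so that
out-of-disk reconstructions remain invertible.  Each spherical channel
carries its own rotation.

## Unsupervised phase extraction

Both extractors map a sliding window (default 7 samples × 11 flattened
dimensions, per-dimension standardized) to a point on the unit circle;
φ = atan2(y, x) mod 2π.  The window's value is assigned to its center
sample; the first/last ⌊w/2⌋ samples copy the nearest computed value.

* **PCA fallback (deterministic, the pipeline default).**  Windows are
  projected onto their two leading principal components, whitened so the
  loop in that plane is near-circular, and the planar angle is the phase.
  For quasi-periodic signals with a dominant fundamental the top two
  components approximate the quadrature pair (cos φ, sin φ), making the
  angle a monotone reparametrization of the cycle.
* **Neural extractor.**  A fully connected network (5 hidden layers × 30
  tanh units, 2 linear outputs; manual-backprop numpy implementation with
  Adam) is trained without labels in two stages: (1) self-supervised
  regression onto the PCA fallback's circle points (a data-derived
  initialization — no external information enters); (2) fine-tuning with a
  relational objective on consecutive window pairs with three terms —
  unit-norm regularization (‖output‖ → 1), forward progression (penalize
  negative and widely varying angular increments sin Δφ between consecutive
  windows), and coverage (batch penalty on the first and second circular
  moments, pushing the angle distribution to spread over the circle and
  preventing phase collapse).  Loss weights default to 1/4/1/1
  (norm/forward/variance/coverage); gradients are verified against finite
  differences in the test suite.  Training is deterministic under its seed.

Both extractors satisfy the same contract, which is what the pipeline
relies on: on clean held-out synthetic data the extracted angle attains
circular correlation ≥ 0.9 with the latent phase after direction
calibration (measured: ≈ 0.96–0.98 for both).  Circular correlation is the
Fisher–Lee coefficient in its pairwise form — the circular-mean-based form
is undefined when phases cover the circle uniformly.

The learned phase has an arbitrary global offset and direction.  Direction
is fixed by negating the y output if the median increment on a normal
reference is negative.  The offset is left alone: circular DTW is
offset-free, so only *where in the cycle* period boundaries fall depends on
it (see Segmentation).

Smoothing: a centered moving average (default window 7, shrinking at the
edges) of the circle points, renormalized to the circle; if antipodal
samples cancel the average to ~0, the previous smoothed value is kept.

## Circular DTW and the ACMP phase

The smoothed phase sequence (length m) is matched against a circular
template of n = 50 evenly spaced phases.  The distance between two phases is
the wrap-aware D(a, b) = min(|a−b| mod 2π, 2π − |a−b| mod 2π) ∈ [0, π].
The cumulative-cost table lives on a cylinder: the allowed moves are the
three standard DTW moves with the template index taken modulo n, so one
template round is reused for every repetition.  Column 0 holds bare local
distances for all rows (free start phase) and the path ends at the
minimal-cost row of the last column (free end).  The vertical move creates
a cyclic dependency within each column; it is resolved by sweeping the
column to a fixed point (two sweeps in practice, capped at n).  Complexity
is O(m·n).

Traceback picks, at each cell, the minimal-cost predecessor with
deterministic tie-breaking: least template advance first ((i, j−1), then
(i−1, j−1), then (i−1, j)); vertical chains are capped below one full
circle per column (a full-circle match within one sample adds the whole
column's local cost and is never optimal, since at most one row per column
has zero local distance).  Per sample j, the matched rows form one
consecutive (unwrapped) run; the ACMP phase is 2π(i_mid mod n)/n with i_mid
the lower-middle row of the run.

Correctness gate: on >200 random instances (n ≤ 6, m ≤ 8) the DP cost and
the traceback path cost equal exhaustive enumeration of all forward-
monotone cylindrical paths (recursive enumeration with an admissible
cost-bound prune; prune-off equivalence is itself tested).

The per-sample **phase-fluctuation score** is D(raw extracted phase, ACMP);
the raw (unsmoothed) phase is scored so that genuine jitter is not averaged
away.

## Segmentation

Period boundaries are the samples where the ACMP template round increments
(the run crosses from row n−1 to row 0).  Segments partition [0, m); the
first and last are flagged partial and are excluded from model fitting and
from false-positive counting, but still scored.

Because the extractor's zero phase is arbitrary, detected boundaries sit at
a fixed latent phase c rather than at the latent 0.  Ground-truth
comparisons therefore estimate c (circular mean of the latent phase at the
detected boundaries) and measure distances to the latent crossings of c;
with c = 0 this reduces to the plain 2π-crossing comparison.  Measured on
clean 40-repetition sessions: period count within ±1 and 100 % of
boundaries within ±3 samples.  Note that adding a constant to all phase
angles *moves* the boundary locations (to where the shifted phase crosses
zero) while leaving the matching cost and the per-sample scores unchanged —
the invariants the tests assert are cost/score invariance under offsets of
2πk/n and AUC invariance under joint monotone transforms of the scores.

## Reconstruction error

Each segmented period is warped onto n standard slots using the CDTW runs:
slot i averages every sample whose run covers template row i (spherical
channels averaged in the AZEQ plane — locally near-Euclidean around the
data mean, an explicit approximation); empty slots are filled by linear
interpolation along the circular slot axis.  Per channel, the warped period
flattens to an N_c-vector (N_c = 2n spherical, n scalar), standardized per
dimension (SD floored at 1e−8), and reconstructed through ĉ = UᵣᵀUᵣc where
Uᵣ holds the smallest set of leading principal components with cumulative
explained variance ≥ 0.95 (a per-channel dimensionality bottleneck; PCA on
the standardized vectors).

The inverse chain un-standardizes, un-warps (each sample takes its slot's
value — piecewise-constant inverse, matching the sample-to-sample error
definition), and AZEQ-unprojects.  Errors are the vector angle (spherical)
or |difference| (scalar), per sample per channel.  Each error is divided by
the square root of the training mean-square error at the same phase bin
(the same n bins as the template; bins with < 3 training samples borrow the
channel's global mean square; everything floored at 1e−12).  Scaled
training errors thus have mean square 1 per bin per channel by
construction, which puts all channels and phases on one scale and justifies
a single global threshold.  Dividing by the RMS (rather than the mean
square itself) is the choice that makes the scaled scores dimensionless
with unit second moment.

## Detection and evaluation

Flags: sample j is anomalous if phase_score[j] > θ_phase OR
max_channel |scaled_error[j]| > θ_recon.  Event-level counting: an event is
detected (TP) if ≥ 1 of its samples is flagged; a normal period (full
period overlapping no event) is a false positive if ≥ 1 of its samples is
flagged.  TPR = detected events / events; FPR = FP periods / normal
periods.  A grid of 50 quantile-spaced thresholds per stream (with
flag-everything and flag-nothing endpoints) produces a point cloud; its
upper-left Pareto frontier, anchored at (0,0) and (1,1), is the ROC, and
the trapezoid rule gives the AUC.  The F1-optimal grid point is reported,
ties resolved toward lower FPR.  Because detection depends only on score
order, the curve is invariant under strictly monotone transforms applied to
the scores.

Cross-validation is leave-subjects-out: subjects are partitioned into k
folds (seeded permutation); each fold's model is built from the normal
sessions of the other subjects and applied to the held-out subjects'
mixture sessions; test scores are pooled across folds for the pooled ROC,
and per-fold curves are also reported.

**HMM baseline.**  A Gaussian-mixture-emission HMM (10 hidden states, 5
mixture components, unrestricted covariances; `hmmlearn`) is trained by EM
on the same standardized 11-dimensional features.  EM with this many full
covariances can collapse a component onto a few samples; fitted covariances
are repaired by eigenvalue flooring (1e−6, with a 1e−3 retry).  Scoring
slides a 30-frame window (1 s) with stride 1; the anomaly score is the
negative length-normalized log-likelihood, aligned to the window center
(alignment is a package choice).  Emission log-likelihoods are computed
once per session and the per-window forward passes are batched — verified
identical to per-window scoring to machine precision.  The default EM
budget is 25 iterations, a deliberate scale-down of the classical
1000-iteration budget to the package's problem sizes; the baseline's AUC is
insensitive to further iterations on this data.

## Synthetic data generator

The simulator is the package's study stand-in: a latent phase oscillator
advances through repetitions whose periods are drawn per repetition from a
slow/medium/fast mix (1.5/2.0/3.0 s, 8 % jitter), occasionally pausing
mid-cycle (probability 0.05 per repetition, 0.3–1.0 s); every channel is a
fixed low-order Fourier function of phase (spherical channels trace closed
loops around a mean direction, renormalized to the sphere) with
per-subject amplitude factors (SD 0.10) and offsets (SD 0.05) drawn once
per subject, plus additive Gaussian noise (SD 0.02).  The scalar templates
include a quadrature pair (wrist x ~ cos φ, wrist y ~ sin φ), as any
closed-loop movement does.

Anomalies are injected as extra repetitions carrying one labeled event
window (default 40 % of the cycle, raised-cosine on/offset): jerk/shake add
a 4.5/7 Hz transient to wrist, pronation, and pointing channels; overshoot/
undershoot scale the deviation from the channel offset by 1 ± magnitude on
the distal channels (restricted range of motion scales all scalars);
compensation adds an offset to the torso channels; path deviation blends
toward an alternative template.  Default magnitudes (0.8, 0.6, 0.7, 0.6,
0.5, 0.25 rad, 0.8) were set once to produce perturbations of roughly half
to one channel amplitude — clearly present, not caricatural.  Random draws
are made unconditionally so that a magnitude-0 twin consumes the identical
stream: outside the event window the two sessions agree exactly, which is
how event confinement is tested.

What the generator does *not* emulate: biomechanical constraints and joint
limits, sensor-specific artifacts (depth-camera jumps, IMU drift),
correlated structured variability between repetitions (fatigue, learning),
and anomaly classes that alter timing without altering shape.  Passing the
synthetic benchmark therefore demonstrates the pipeline's mechanics —
segmentation without templates, cross-channel score calibration,
event-level ranking — not clinical detection performance on real capture
data.

## Benchmark scale and measured results

The default benchmark uses 12 subjects, 6-fold leave-subjects-out, test
sessions of 40 normal + 6 anomalous repetitions (one event per anomaly
type: jerk, shake, overshoot, undershoot, restricted range of motion,
compensation), and 25 training repetitions per subject — the training size
is the package's scale choice; more repetitions only sharpen the channel
models.  With seed 1 the acceptance script measures: pooled AUC 0.992 for
the two-stream detector vs 0.741 for the HMM baseline; best-F1 operating
point 0.892 (precision 0.925, recall 0.861); phase circular correlation
0.983 (network) / 0.957 (fallback); segmentation period-count error ≤ 1
with 100 % of boundaries within ±3 samples; error-scaling calibration exact
to machine precision.  All quantities are recomputed from scratch by
`scripts/acceptance.py`.

## Numerical and design choices

* Angles in radians, positions in meters, time in sample index; seconds via
  the frame rate.
* All randomness flows through `numpy` generators seeded per command;
  identical configuration + seed reproduces outputs bit-for-bit.
* PCA via scikit-learn with the full SVD solver (deterministic); rotation
  construction via scipy.
* i_mid for even-length runs takes the lower middle; wrap-crossing runs are
  unwrapped before taking the middle.
* The model bundle (rotations, extractor weights, per-channel
  standardization/Uᵣ/error scales) persists as JSON metadata + npz arrays,
  with a format version checked on load.

## Known limitations

* The reconstruction detector's sensitivity to pure amplitude-scaling
  anomalies drops when the PCA bottleneck retains many components (noisy
  training data widens the bottleneck — the same data-quality effect that
  separates capture systems).
* Period boundaries inherit the extractor's arbitrary zero phase; they are
  consistent within a session but not anchored to a semantic cycle start.
* The AZEQ plane average during warping is biased for loops spanning large
  polar angles.
* One exercise per model: no multi-template matching, no online scoring.
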