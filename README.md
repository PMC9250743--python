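# repanom

Unsupervised modeling and anomaly scoring of repetitive rehabilitation
exercises from multi-channel kinematic time series.

## The problem

Home-based stroke rehabilitation produces long recordings of repetitive
upper-limb exercises that no therapist has time to review frame by frame.
`repanom` builds a model of the *normal* movement from a small group of
healthy subjects — using only unsegmented, unlabeled recordings — and then
converts a new exercise session into a compact per-sample anomaly
representation: repetition boundaries plus two anomaly score streams that
point the reviewer at the few seconds worth watching.  It is aimed at
researchers and engineers building exercise-monitoring / telerehabilitation
pipelines from markerless or marker-based motion capture.

## Method

A session is nine kinematic **feature channels** sampled at 30 fps: upper-arm
and forearm pointing directions (3D unit vectors in the upper-torso frame),
three torso angles, forearm pronation, and the wrist position in a static
*core* frame.  The pipeline:

1. **AZEQ flattening.**  Each spherical channel is rotated so its training
   mean sits at the north pole and mapped by the azimuthal equidistant
   projection `p = θ·(cos α, sin α)`, an invertible 2D representation whose
   tear is at the (rarely visited) south pole.
2. **Unsupervised phase.**  A small network (or a deterministic
   two-principal-component fallback) maps each 7-sample window of the
   11-dimensional flattened features to a point on the unit circle;
   `φ = atan2(y, x) mod 2π` is the movement phase.  No labels or
   pre-segmentation are used.
3. **Circular DTW.**  The smoothed phase sequence is matched against a single
   circular template `template[i] = 2πi/n` (n = 50) whose index axis wraps,
   so one 0→2π round is reused for every repetition.  The optimal cylinder
   path yields the *approximately closest monotonically progressing* (ACMP)
   phase; the circular distance between the raw extracted phase and the ACMP
   phase is the **phase-fluctuation score**, and ACMP wraps delimit
   repetition periods.
4. **PCA reconstruction error.**  Each period is warped to n standard slots,
   standardized per channel, and passed through the bottleneck
   `ĉ = Uᵣᵀ Uᵣ c`, where `Uᵣ` holds the fewest principal components
   explaining ≥ 95 % of the training variance.  The reconstruction is
   inverted back to original units and length; per-sample errors (vector
   angle for spherical channels, |difference| for scalars) are divided by
   the training RMS error at the same phase bin, giving the
   **scaled reconstruction-error score** — comparable across channels and
   phases, so one global threshold suffices.
5. **Event-level evaluation.**  A sample is flagged when either score
   exceeds its threshold.  An anomaly event counts as detected if any of its
   samples is flagged; a normal period counts as a false positive if any of
   its samples is flagged.  Sweeping both thresholds yields an ROC (Pareto
   frontier of the grid) and its AUC; a sliding-window Gaussian-mixture HMM
   (10 states, 5 mixtures) provides the baseline.

A built-in simulator generates multi-subject sessions from a latent phase
oscillator (slow/medium/fast repetitions, mid-cycle pauses, between-subject
variation, additive noise) with labeled anomalous repetitions — jerks,
shaking, overshoot, undershoot, restricted range of motion, torso
compensation, path deviation — so the whole pipeline is testable without
capture hardware.

## Worked example

Train a model on eight healthy subjects' normal sessions, then score a new
subject's session containing one injected jerk:

```python
from repanom import (SimConfig, AnomalySpec, generate_session,
                     fit_exercise_model, run_pipeline, PipelineConfig)
from repanom.evaluate import session_scores

cfg = SimConfig(pause_probability=0.0, noise_sd=0.01)
train = [generate_session(cfg, f"S{i}", i).features for i in range(8)]
model = fit_exercise_model(train, PipelineConfig(), seed=0)

test_cfg = SimConfig(pause_probability=0.0, noise_sd=0.01, n_repetitions=12,
                     anomaly_spec=(AnomalySpec("jerk", 1.0, 0.4),))
session = generate_session(test_cfg, "patient", 31)
report = run_pipeline(session.features, model)

print("periods found:", len(report.segments))
s, e, kind = session.anomaly_events[0]
print(f"labeled {kind} event at samples [{s}, {e})")
sc = session_scores(report.phase_score, report.recon_scores,
                    session.anomaly_events, report.segments)
print(f"scaled recon error, anomalous repetition : {sc.event_recon_max[0]:.1f}")
print(f"scaled recon error, worst normal period  : {sc.period_recon_max.max():.1f}")
print(f"phase score, anomalous repetition        : {sc.event_phase_max[0]:.3f}")
print(f"phase score, worst normal period         : {sc.period_phase_max.max():.3f}")
```

prints

```
periods found: 14
labeled jerk event at samples [49, 72)
scaled recon error, anomalous repetition : 34.1
scaled recon error, worst normal period  : 4.2
phase score, anomalous repetition        : 0.161
phase score, worst normal period         : 0.097
```

The 13 repetitions (12 normal + 1 anomalous) appear as 12 interior periods
plus two partial edge segments.  The jerk drives the scaled reconstruction
error to 8× the worst normal period — any threshold between ~5 and ~34
flags exactly that repetition.  Training on too few subjects (say 3) raises
the normal background substantially: generalization to unseen subjects is
the reason the model wants 8–12 training subjects.

The same pipeline is available from the shell:

```bash
repanom simulate --out data/ --subjects 2 --reps 40 --seed 1
repanom train    --train data/ --out model/ --seed 1
repanom detect   --model model/ --in data/S00.csv --out det/ \
                 --theta-phase 0.5 --theta-recon 10
repanom evaluate --subjects 12 --folds 6 --out report/ --seed 1
repanom plot     --model model/ --in data/S00.csv --out fig.png
```

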