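# Methods

## Problem and data model

Freezing of gait (FOG) is scored per sample: a walk is a synchronized
multi-sensor IMU recording (6 channels per body location: accelerometer
x/y/z in m·s⁻², gyroscope x/y/z in rad·s⁻¹) with a binary FOG label per
sample. Eleven wear locations are supported (head, chest, lumbar, both
wrists, thighs, ankles, feet); a recording may carry any subset. On disk a
walk is one CSV (`time_s`, `{location}_{acc|gyr}_{x|y|z}`, `label`), a
cohort a directory with a `participant_id, walk_id, path` manifest. CSV was
chosen over vendor formats so every byte of the pipeline is inspectable and
testable.

Recordings nominally arrive at 128 Hz and are analyzed at 64 Hz. The
decimation method is a zero-phase 8th-order Butterworth low-pass at
0.45 × target rate followed by taking every factor-th sample; labels are
decimated by the same index selection, so a retained sample never changes
its label. Only integer decimation factors are supported.

## Synthetic cohorts

The generator produces labeled cohorts with the minimal statistical
structure a windowed FOG detector must exploit; it makes no attempt at
biomechanical realism.

- **Episode schedule.** Per walk, a two-state alternating renewal process:
  episode durations log-normal (default mean 5 s, σ = 0.5 on the log
  scale), gap durations log-normal with mean chosen so long-run occupancy
  equals the participant's freezing propensity. The process starts a few
  cycles before t = 0 to approximate stationarity, so mean occupancy over
  many walks tracks the propensity (±0.03 at 1000 draws of a 90-s walk).
- **Signals.** While walking, each channel carries a locomotor oscillation:
  step fundamental (default 1.0 Hz, jittered ±0.15 Hz per participant) plus
  two harmonics with random phases, scaled by a per-location gain. During
  FOG the locomotor amplitude is multiplied by 0.1 (≥ 80 % suppression
  enforced) and leg locations (thighs, ankles, feet) gain a band-limited
  3–8 Hz "trembling" component scaled by the same gain. White Gaussian
  noise (σ = 0.5) is added everywhere. Default gains: ankles 1.0, feet 0.9,
  thighs 0.8, lumbar 0.75, chest 0.45, wrists 0.15, head 0.05 — legs and
  lumbar informative, wrists and head near-noise.
- **Cohort shape defaults** emulate a small Parkinson's cohort on a
  freeze-eliciting course: 7 participants, 5–14 walks of 90 s at 128 Hz,
  per-participant freezing propensities spanning ~0.10–0.54 (pooled
  occupancy lands in the realistic 15–35 % range).

What the generator does *not* emulate: turning geometry, stride-to-stride
variability, sensor drift/saturation, gait-initiation freezes, and the
correlation structure of real multi-axis signals. Passing tests therefore
demonstrate that the pipeline recovers planted, spectrally well-separated
structure — not field performance on recorded patients.

## Windowing

Walks are cut into 2-s windows that never span walk boundaries. The stride
is the largest value on a 1-sample grid whose closed-form count
Σ⌊(Tᵢ−L)/s⌋+1 reaches a target (default 10,000), found by binary search; an
infeasible target raises an error reporting the achievable maximum. Each
window's label is the majority of its sample labels, with exact ties
labeled FOG (favoring sensitivity). Channels are normalized per window to
zero mean and unit **population** variance; constant channels map to zeros.
Rotation augmentation draws, per sensor, three angles uniform in
[−θ, θ] and composes the axis rotations in x→y→z order into one orthonormal
matrix applied jointly to the accel and gyro triplets (sample norms
preserved to 1e-9). Augmentation is applied to *raw* windows, then
normalization — the reverse would distort the rotational geometry. The
package default is θ = π (arbitrary orientation); see "study protocols" for
the desk-scale override. Loss weights are 0.5/n_{p,c} per participant
p and class c; a participant lacking a class is reported by name rather
than silently reweighted.

## Network and training

Two same-padded 1D conv layers (16 filters, kernel 17, ReLU, dropout 0.5
after each), max-pool 2, dense 10 (ReLU), dense 1 (sigmoid). Implemented in
NumPy with im2col convolutions and an analytically derived backward pass
(verified against numerical differentiation to <2 % relative error in
float32); the optimizer is standard Adam (lr 1e-3, β = 0.9/0.999). The loss
is weighted binary cross-entropy computed on logits. Each fold early-stops
when the held-out participant's loss fails to improve for `patience`
epochs (default 10, max 100) and restores the best-loss parameters.
Early stopping on the *test* subject's loss is retained deliberately for
fidelity to the validation design it reproduces; it is optimistic, and a
deployment would hold out a separate tuning subject.

All randomness flows from explicit seeds: fold seed = global seed +
1000 × repeat + fold index. Single-threaded CPU runs are bit-reproducible.

## Sensor-set experiments

Every candidate subset is evaluated on identical windows (same stride and
start grid; only channel rows differ), so comparisons are paired. Summary
statistic: mean AUROC over folds, then over repeats. The *best technical
set* maximizes mean AUROC (ties → fewer sensors, then lexicographic). The
*minimal set* is the smallest subset with mean AUROC ≥ (1 − 0.05) × best —
the 5 % tolerance is interpreted **relative** to the best set's AUROC, and
is configurable. AUROC and average precision are computed via
scikit-learn; the test suite checks them against brute-force pair-count
and threshold-sweep oracles.

## Clinical layer

Evaluation "examples" are non-overlapping 2-s windows. Probabilities are
thresholded strictly (`p > τ`), then post-processed in the stated order:
(1) merge FOG runs separated by exactly one non-FOG example, iterated to a
fixed point (a merge can create a new one-example gap); (2) delete runs one
example long. Order matters — on (0,1,0,1,1,0,0,1,0) merge-then-delete
yields one 4-example event, whereas delete-then-merge would first remove
both short runs. Percent time FOG = total event duration / walk duration ×
100; events = count of non-FOG→FOG transitions (a walk starting frozen
counts one). Ground-truth metrics use the example-level human labels as-is,
with no thresholding or post-processing.

Agreement uses ICC(1,1) — one-way random effects, single rating, absolute
agreement — computed from the ANOVA decomposition with a two-sided 95 % CI
from F-quantiles; all-identical ratings return a flagged degenerate result
instead of dividing by zero. Reliability classes follow the CI: < 0.50
poor, 0.50–0.75 moderate, 0.75–0.90 good, > 0.90 excellent; a CI spanning
bands reports the range ("good to excellent"). The decision threshold is
optimized per metric over the grid 0.00–1.00 (step 0.01), ties broken
toward the lower (more sensitive) threshold.

## Study protocols

`studies.py` defines two scales:

- **paper scale** — the generator defaults above; suitable for overnight
  experiments with 30 LOSO repeats.
- **desk scale** — the protocol used by the bundled experiments and the
  results script: 4 participants × 3 walks × 30 s synthesized directly at
  64 Hz (propensities 0.20–0.54), ~500 overlapping windows, batch 32,
  ≤ 12 epochs with patience 6, one repeat, and rotation augmentation
  limited to ±30° (realistic mounting variation). The last choice matters:
  with arbitrary ±180° rotations the model needs a much larger epoch budget
  to learn orientation-invariant features (measured mean LOSO AUROC ~0.89
  at 25 epochs, vs 0.99 at ±30° with 12), so the compact protocol trades
  augmentation aggressiveness for wall-clock time. The clinical study uses
  4 × 60-s walks per participant because walk-level ICC needs more rating
  targets than window-level scores do.

## Numerical notes and limitations

- Training tensors are float32; metrics and ICC are float64.
- AUROC is undefined for a single-class held-out participant; such folds
  are recorded as missing and excluded from summaries (logged, not hidden).
- Percent time FOG is not strictly monotone in the threshold once events
  are merged/deleted; the optimizer treats each threshold independently, so
  this is harmless.
- Event-count agreement (ICC of n_events) is weak on short synthetic
  walks: with 2-s examples and ~5-s episodes, boundary effects dominate the
  count. This mirrors the general observation that event counts are a
  harder target than time-in-state.
- The NumPy trainer is single-threaded by design for reproducibility; it is
  not suitable for cohorts beyond a few hundred thousand windows.
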