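# fogdetect

Detection of **freezing of gait (FOG)** from raw wearable inertial sensor
signals. Freezing — the episodic inability to produce alternating stepping
that affects many people with Parkinson's disease — is conventionally scored
by experts from video. `fogdetect` implements an automated alternative: a
small one-dimensional convolutional neural network that classifies 2-s
windows of raw IMU data (tri-axial accelerometer + gyroscope per body
location), validated leave-one-subject-out, together with the analyses that
make such a detector useful in practice:

- **sensor-set comparison** — which IMU subsets detect FOG best, selecting a
  *best technical set* (highest mean held-out AUROC) and a *minimal set*
  (fewest sensors within 5 % of the best);
- **clinical metrics** — converting window probabilities into per-walk
  *percent time FOG* and *number of FOG events* via threshold + event
  post-processing, and quantifying agreement with ground-truth ratings using
  the intraclass correlation ICC(1,1) with Koo reliability bands;
- a **synthetic cohort generator** that plants the FOG phenomenology
  (suppressed locomotion plus 3–8 Hz leg trembling, location-dependent
  informativeness), so the whole pipeline is testable end-to-end without any
  recorded data.

The package is primarily a Python library (see `examples/`), with a thin
`fog-detect` CLI (`simulate`, `train`, `evaluate`, `clinical`, `run-all`).

## The model

Windows are $x \in \mathbb{R}^{C \times 128}$ (2 s at 64 Hz, $C = 6\,|S|$
channels for sensor set $S$), each channel normalized to zero mean, unit
variance. The classifier is

```
conv1d(16 filters, kernel 17, ReLU, same) → dropout 0.5
conv1d(16 filters, kernel 17, ReLU, same) → dropout 0.5
max-pool(2) → flatten → dense(10, ReLU) → dense(1, sigmoid)
```

trained with weighted binary cross-entropy (Adam, learning rate $10^{-3}$,
batch 512). A window of participant $p$ and class $c$ carries weight
$0.5/n_{p,c}$, so each participant's weights sum to 1 and each class within
a participant to 0.5. Training windows are re-augmented every epoch with
random per-sensor rotations. Validation is leave-one-subject-out (LOSO):
every fold holds one participant out entirely and early-stops on that
participant's loss. The network and its optimizer are implemented in NumPy
(`fogdetect.nn`) — the model is small enough (~16k parameters) that no deep
learning framework is needed.

## Worked example

`examples/03_compare_sensor_sets.py` runs the desk-scale sensor comparison
(4 synthetic participants, 3 × 30-s walks, ~500 overlapping windows, one
LOSO run per candidate set):

```
sensor set                   mean AUROC  mean AP
ankle_L+ankle_R                   0.999    0.999
ankle_L                           0.997    0.996
lumbar                            0.980    0.978
lumbar+ankle_L+ankle_R            0.976    0.976
chest                             0.796    0.702
head                              0.531    0.429
wrist_L                           0.520    0.398

best technical set: ['ankle_L', 'ankle_R'] (AUROC 0.999)
minimal set:        ['ankle_L'] (AUROC 0.997, 0.2 % from best)
```

Mean AUROC is the probability that a FOG window of an *unseen* participant
outranks a non-FOG window. The ranking recovers the informativeness planted
by the generator: leg sensors carry the trembling signature, the head and
wrist are near chance (0.5). A single ankle IMU is within 5 % of the best
set, so it is selected as the minimal deployable set.

`examples/04_clinical_agreement.py` continues to the clinical layer:

```
percent_time : threshold 0.49, ICC 0.887 [0.71, 0.96] -> moderate to excellent
n_events     : threshold 0.49, ICC 0.546 [0.10, 0.81] -> poor to good
```

The percent-time-FOG ICC of 0.89 means single-walk model readings agree
with ground truth about as well as two human raters typically do; event
*counts* are harder on short synthetic walks because the 2-s example grid
blurs episode boundaries.

## Layout

| path | contents |
|---|---|
| `src/fogdetect/signal_io.py` | CSV walk/cohort I/O, 128→64 Hz decimation |
| `src/fogdetect/synthetic.py` | synthetic cohort generator |
| `src/fogdetect/windowing.py` | stride search, segmentation, normalization, rotation augmentation, loss weights |
| `src/fogdetect/nn.py` | NumPy 1D-CNN, Adam, early stopping |
| `src/fogdetect/fog_net.py` | model config, fold training, LOSO |
| `src/fogdetect/evaluation.py` | AUROC/AP, sensor-set experiments, set selection |
| `src/fogdetect/clinical.py` | thresholding, event post-processing, ICC(1,1) |
| `src/fogdetect/pipeline.py`, `cli.py` | end-to-end orchestration, `fog-detect` CLI |
| `src/fogdetect/studies.py` | paper-scale and desk-scale study protocols |

See `docs/methods.md` for the modelling assumptions, parameter choices and
known limitations.
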