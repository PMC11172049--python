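# retwave

Wavelet-CNN spectral features for grading diabetic retinopathy (DR) from
retinal fundus photographs, with classical classifier heads.

DR severity is scored on the five-grade ICDR scale — 0 (no apparent
retinopathy) to 4 (proliferative DR) — from the presence and extent of
microaneurysms, exudates and haemorrhages. Ordinary CNNs grade from spatial
features only; this package implements a hybrid that injects exact spectral
structure into the network: a 2-D Haar multiresolution analysis (MRA) of the
input image is computed alongside the convolutional trunk, and at every scale
the four sub-band planes are concatenated channel-wise into the feature maps
of matching size. The trunk's global-average-pooling (GAP) vector is then
classified either by the network's own softmax head or by a classical head —
RBF support vector machine, random forest, or gradient boosted trees.

## The model

A single MRA level splits the approximation plane with an orthonormal
low-pass/high-pass pair (k_l, k_h) followed by dyadic downsampling:

    X_{l,t+1} = (X_{l,t} * k_l) ↓2
    X_{h,t+1} = (X_{l,t} * k_h) ↓2

With the Haar pair (taps ±1/√2) the transform is exact, energy-preserving
(Parseval) and perfectly invertible. A plain CNN is the constrained version
of this recursion that discards X_h at every level; the architecture restores
the discarded detail channels by injection. The trunk follows VGG
conventions: all convolutions are 3×3 with padding 1; spatial resolution is
halved only by stride-2 convolutions (no pooling); each injection is followed
by a 1×1 projection convolution that restores the stage width; batch
normalisation precedes every ReLU; GAP replaces fully connected layers.
The default 224×224×3, T=4, 5-class instantiation has exactly **11,799,109**
trainable parameters (stem 64, stage widths 128/256/456/572, feature
convolution 355 — calibrated once to that budget and frozen).

Because no deep-learning framework is assumed, the network itself (layers,
backpropagation, Adam) is implemented on NumPy; desk-scale configurations
train in seconds on one CPU and are bit-reproducible given a seed.

Evaluation reports per-class and macro precision / recall / F1 from the
one-vs-rest counts, accuracy, and per-class ROC curves with trapezoidal AUC.

## Worked example

No clinical data is bundled; the package ships a seeded synthetic fundus
phantom generator (bright disc, wavy vessels, grade-dependent
microaneurysm-, exudate- and haemorrhage-like lesions: 0/3/8/16/28 lesions
for grades 0–4). The full protocol — simulate, stratified 80/20 split,
augmentation balancing of the training side, end-to-end training, GAP
feature extraction, one classical head per flavour, held-out evaluation —
runs from the command line:

```sh
retwave e2e --tiny --seed 0 --out runs/demo
```

which trains the 64×64/T=2 configuration on 5×50 phantoms (~25 s on one CPU)
and prints the held-out comparison:

```json
{
  "svm":           {"accuracy": 0.94, "macro_f1": 0.9398, "macro_auc": 0.992},
  "random_forest": {"accuracy": 0.92, "macro_f1": 0.9192, "macro_auc": 0.991},
  "xgboost":       {"accuracy": 0.90, "macro_f1": 0.8946, "macro_auc": 0.9715},
  "softmax_head":  {"accuracy": 0.88, "macro_f1": 0.8800, "macro_auc": 0.9835}
}
best head: svm
```

(abridged; the full per-head reports, confusion matrices and ROC points are
written under `runs/demo/`). The margin classifier on GAP features beats the
network's own softmax head — the motivation for the hybrid design. Other
commands: `retwave simulate`, `params`, `train`, `features`, `classify`,
`evaluate`; `retwave params` prints the audited layer table and total
parameter count.

Library use mirrors the CLI:

```python
from retwave import pipeline
result = pipeline.run_end_to_end(pipeline.tiny_run_config(seed=0))
print(result["summary"]["svm"]["macro_f1"])
```

## Acceptance script

`scripts/acceptance.py` rebuilds the default grading architecture from
scratch and recomputes its headline quantity (the trainable-parameter
count), writing a JSON report:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `retwave.wavelet` — exact 2-D Haar MRA: single-level analysis, iterated
  decomposition, perfect reconstruction.
- `retwave.nn` — minimal NumPy layers with explicit backprop (conv, BN,
  ReLU, GAP, linear, Adam).
- `retwave.model` — the Wavelet-CNN: layer table, building, training,
  feature extraction, checkpoints.
- `retwave.classify` — classical heads and the evaluation suite.
- `retwave.data_io` — EyePACS-dialect manifests, contrast enhancement,
  resize/crop/flip preprocessing, augmentation balancing, splits.
- `retwave.synthetic` — the phantom generator.
- `retwave.pipeline` / `retwave.cli` — orchestration and the `retwave`
  command.

See `docs/methods.md` for the modelling choices, defaults and limitations.
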