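# Methods

## The Haar multiresolution analysis (`retwave.wavelet`)

One analysis level maps a plane to four half-resolution sub-bands by
separable filtering with a two-tap pair followed by dyadic downsampling.
Conventions, fixed once:

- **Normalisation.** Orthonormal taps, k_l = (1, 1)/√2 and k_h = (1, −1)/√2.
  This makes Parseval's identity exact (sub-band energy = input energy) and
  the inverse transform the transpose of the forward one, so the
  perfect-reconstruction and energy tests run at 1e−10 tolerances without
  any rescaling bookkeeping.
- **Phase.** Filtering is anchored at even samples: y[n] combines x[2n] and
  x[2n+1]. Downsampling keeps even output indices (0-based).
- **Sub-band naming.** `(row filter, column filter)`: `lh` = low-pass along
  axis 0, high-pass along axis 1; `hl` the converse. The brute-force oracle
  in the test-suite encodes the same convention independently.
- **Boundaries.** Only even dimensions are legal for one level, and
  2^T-divisible dimensions for depth T; there is no padding scheme. The
  preprocessing chain guarantees 224 = 14·2⁴ (or 64 = 16·2² at desk scale),
  so none is needed. Violations raise errors that name the offending axis
  or state the maximum feasible depth.
- **Colour.** RGB channels are decomposed independently; at each level the
  planes are stacked band-major (ll over channels, then lh, hl, hh), giving
  4·C injection channels.

## The network (`retwave.model`, `retwave.nn`)

Architecture rules: 3×3 convolutions with padding 1 everywhere; stride-2
3×3 convolutions (padding 1) do all downsampling; a 1×1 projection
convolution follows every channel-wise sub-band injection, since
concatenation changes the channel count; batch normalisation before every
ReLU; global average pooling instead of fully connected layers; a linear
5-way softmax head for end-to-end training. Per decomposition level the
stage is: stride-2 downsample → inject 4·C sub-band channels → 1×1
projection → 3×3 same-scale convolution, each convolution with BN+ReLU.

**Width calibration.** Only the total trainable-parameter budget of the
224/T=4/5-class instantiation is pinned (11,799,109); the per-stage widths
are otherwise free. An integer search over VGG-style families (doubling
early widths, free last-stage and feature widths) produced the frozen
table: stem 64, stages (128, 256, 456, 572), feature convolution 355, GAP
dimension 355. The count is verified exactly in the tests by a closed-form
recomputation from the exported layer table, independent of the array
shapes.

**Why NumPy.** The execution environment provides no deep-learning
framework, so `retwave.nn` implements the six needed primitives with
explicit backpropagation. Convolution uses strided sliding-window views and
`einsum`; the input gradient is accumulated per kernel tap (9 matrix
products for a 3×3 kernel). Everything is float32 and single-threaded
deterministic: two runs with one seed agree bit-for-bit, which the spec of
the training contract requires. The cost is speed at full scale —
training the 224-pixel network on a real corpus is out of scope — but
desk-scale configurations (64 px, ~11k parameters) train in seconds.

**Training.** Adam (lr 1e−3, β = 0.9/0.999), softmax cross-entropy,
batch 32 (25 at desk scale), max 50 epochs. Early stopping monitors
training accuracy with patience 5 and restores the best weights; training
also halts once accuracy reaches 1.0 (no further signal). The monitored
quantity is the running training accuracy over the epoch's mini-batches
(networks in training mode), the cheap and standard choice. Sub-band
stacks depend only on the inputs and are computed once per training set,
not per epoch.

**Feature extraction** always runs in evaluation mode (BN running
statistics, deterministic preprocessing, no crop/flip randomness), so a
duplicated image yields identical rows.

## Classifier heads and metrics (`retwave.classify`)

- SVM: RBF kernel (the package follows the convention that the kernel
  width γ matters, which only kernelised SVMs have), C = 1, γ = "scale";
  a small cross-validated grid utility is provided since no published
  values exist. Per-class scores are a softmax link over the one-vs-rest
  decision values — monotone in the margins, so ROC/AUC are unaffected by
  the link; `SVC(probability=True)` was avoided as deprecated upstream.
- Random forest and gradient boosted trees: 10 estimators by default (an
  anti-overfitting choice at the modest feature dimension). The boosted
  head uses scikit-learn's gradient-boosting implementation.
- Softmax head: multinomial logistic regression on the GAP features,
  equivalent to refitting the network's own linear output layer.

Metrics are computed from the one-vs-rest counts: precision TP/(TP+FP),
recall TP/(TP+FN), F1 the harmonic mean, accuracy trace/sum of the
confusion matrix (rows = true grade). Macro averages are unweighted class
means; this is the headline multiclass summary. ROC curves sweep every
distinct score threshold; AUC is trapezoidal. Degenerate cases: a class
absent from the truth gets NaN recall/F1/AUC and is excluded from macros
with a warning; a class never predicted gets precision 0 with a warning.

## Preprocessing, balancing, splitting (`retwave.data_io`)

- Contrast enhancement is CLAHE on the luminance (Y of YUV) channel, clip
  limit 0.01, tile 8 — the standard treatment for low-contrast retinal
  vasculature — switchable to a plain linear stretch (used at desk scale,
  where phantoms have controlled contrast) or off. Constant images pass
  through unchanged.
- Geometry: resize to 256, then a seeded random 224 crop plus horizontal
  flip (p = 0.5) in training mode, or a deterministic centre crop without
  flip otherwise. Desk scale uses 72 → 64 with the same ratio of context
  to crop.
- Balancing up-samples every minority grade to the majority count — never
  down-samples, never touches originals. Added records store their sampled
  affine descriptor (width/height shift ≤ 0.1 of the side, zoom in
  [0.9, 1.1], optional horizontal flip, nearest-neighbour boundary fill) in
  the manifest's provenance column, so every augmented image re-renders
  bit-exactly from its source; the defaults are conventional magnitudes for
  fundus augmentation.
- The 80/20 split is stratified per grade by default (all five grades stay
  represented in the 20% hold-out), seeded, and order-invariant
  (sort-then-shuffle). Balancing is applied after splitting and only to
  the training partition, so no augmented copy of a held-out image can
  leak into training.

## The phantom generator (`retwave.synthetic`)

A phantom is: dark background; bright warm-coloured disc (radius 0.45 of
the side) with radial shading; six wavy vessel curves radiating from the
centre (soft distance-profile rendering); lesions sampled uniformly inside
the disc. The grade ladder is frozen: microaneurysm-like dark dots
(0/2/4/8/14 across grades 0–4, radius 1.0–1.8% of the side), exudate-like
bright yellow blobs (0/1/3/5/8, 2.0–3.5%), haemorrhage-like dark blotches
(0/0/1/3/6, 3.5–6.0%), all radii scaled by 1 + 0.15·grade; additive
Gaussian noise with σ = 0.01. Within-disc intensity variance is strictly
increasing in grade (tested), so the downstream pipeline has a learnable
but non-trivial signal; adjacent grades overlap visually like mild/moderate
retinopathy does.

What a green end-to-end test establishes: the whole chain — analysis,
injection, training, feature extraction, heads, metrics — is wired
correctly and can learn a five-way severity signal at desk scale. What it
does not establish: clinical performance. Phantoms lack camera vignetting,
illumination gradients, ungradable images, inter-grader label noise and the
severe class imbalance of real screening corpora (balancing is exercised
structurally, not statistically).

## Numerical choices and limitations

- Wavelet tolerances: 1e−10 for oracle equivalence, Parseval and
  reconstruction (float64 path); the network runs float32.
- BN uses batch statistics in training and running averages (momentum 0.1,
  ε = 1e−5) in evaluation.
- Seeds: one master seed fans out to model init, data order, crops,
  augmentation draws, split and phantom rendering via stable SHA-based
  derivation (never `hash()`, which is process-randomised).
- The full 224-pixel network trains only impractically slowly on NumPy;
  the package pins its architecture exactly and trains reduced
  instantiations of the same rules.
- Tree-head determinism holds for a fixed environment; scikit-learn version
  changes may alter tie-breaks.
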