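# Methods

## Problem and pipeline

The package classifies small RGB tissue patches from narrow-band
laryngoscopy into four classes — hypertrophic blood vessels (Hbv), healthy
tissue (He), abnormal intrapapillary-capillary-loop-like vessels (IPCL) and
leukoplakia (Le).  The pipeline is: median-filter denoising → three parallel
convolutional feature extractors whose embeddings are fused by
concatenation → an autoencoder-based classifier over the fused vector →
population-metaheuristic (osprey) tuning of the classifier's
hyperparameters on a validation split.

## Synthetic data

The real dataset (1,320 patches of 100×100 px, 330 per class, from 33
patients) is not redistributable, so the generator emulates its *layout and
statistics*, not its histology: four procedural texture families chosen so
that classes are separable even in trivial statistics (mean RGB), which
makes end-to-end learning verifiable.

* Hbv — thresholded bent sine waves: dark curvilinear filaments, high
  per-channel variance;
* He — band-limited smoothed noise at amplitude ±4 grey levels: the
  low-variance class by construction;
* IPCL — 30–50 small dark disks on a uniform background;
* Le — thresholded smooth random fields: bright irregular blobs.

Defaults reproduce the reference composition (patch side 100, 330 patches
per class, 1,320 total).  Salt-and-pepper corruption is on by default at a
5% pixel fraction so the median-filter stage has an observable effect;
clean textures are clipped to [1, 254], so a corrupted pixel (0 or 255)
always differs from its clean twin — useful for exact noise-mask tests.
Each image derives its RNG from (seed, class, index), making datasets
byte-identical across runs and machines.  Splits default to 70/15/15
stratified by class.  What passing tests do **not** show: robustness to
staining/illumination variation, patient-level effects (patches from one
patient across splits), or any clinical validity — the textures are far
easier than real tissue.

## Preprocessing

Marginal (per-channel) median with an odd square kernel, default 3×3,
reflective borders (an `edge` mode is available).  Per-channel rather than
vector median is standard practice and preserves the order-statistic
property per channel: every output value is one of the input values.  Odd
kernels make median ties impossible.  We filter at native resolution first
and resize afterwards: filtering after downsampling would let impulse noise
bleed into neighboring pixels through interpolation.

## Feature extractors

All three networks take 64×64×3 inputs (bilinear resize of the 100×100
patches, intensities scaled to [−0.5, 0.5]) and are implemented on the
package's own numpy layer library (`laryngofuse.nn`) — NHWC layout, float32,
stride-1 'same' convolutions via im2col, 2×2/stride-2 max pooling,
hand-derived backprop, Adam.

* **AlexNet-style** — conv channels (96, **256**, 384, 384, 256), all 3×3;
  pooling after conv1, conv2 and conv5; FC6 and FC7 with 4096 ReLU units
  and dropout 0.5 each.  Conv2's 256 same-padded 3×3 filters and the
  4096/0.5 FC block are fixed architecture constants; the remaining widths
  follow the canonical architecture scaled to the 64-px input and are
  configurable.  The embedding is FC7 (4096-d); the softmax head used in
  training is dropped for feature extraction.
* **SqueezeNet-style** — 3×3 conv stem, fire modules (1×1 squeeze feeding
  parallel 1×1 and 3×3 expands, concatenated) of widths 64/64/128, dropout,
  a 1×1 conv to the embedding width (default 64) and global average
  pooling.
* **Capsule network** — two-conv stem to a 16×16×32 map, reshaped into
  1,024 primary capsules of 8 components (squashed), transformed by a
  per-pair weight tensor into predictions for 16 output capsules of 8
  components, routed for 3 agreement iterations.  The routing recursion is
  `c = softmax(b)` over parents, `s_j = Σ_i c_ij U_ij`, `v_j = squash(s_j)`,
  `b_ij += U_ij · v_j`; the agreement update rule is the canonical one (the
  routing literature's standard choice).  The embedding concatenates the
  output capsules (128-d); every capsule norm is below 1 by the squash
  bound.

Training: each extractor is trained end-to-end on the task with a temporary
softmax head (Adam, categorical cross-entropy), then frozen.  No external
pretrained weights are required; the builders accept configurable widths
and seeds.  Backpropagation through the capsule layer treats the final
coupling coefficients as constants (gradients flow through the transform
tensor and both squashes but not through the routing recursion); this is
exact for one routing iteration and a standard, stable approximation for
more.  Fusion is concatenation in fixed order (alexnet, squeezenet,
capsnet) with recorded span offsets — the simplest operator consistent with
treating the three embeddings as complementary views.

## Autoencoder classifier

Single affine + activation per side, as the model equations state: encoder
`Z = σ(W_e X + b_e)` (ReLU default, sigmoid available), decoder
`X̂ = σ(W_d Z + b_d)`.  Features are standardized per dimension with
train-split statistics, which makes the decoder's *output* activation
linear by default: a ReLU or sigmoid output layer cannot reach the negative
half of standardized targets, and the identity output keeps the
reconstruction objective well-posed (a linear-activation configuration is
also what makes the latent_dim = input_dim sanity case recover the
identity).  Training minimizes the mean-squared reconstruction error with
Adam; the returned history starts with the pre-training loss so improvement
is certified by `history[-1] ≤ history[0]`, and the best-epoch weights are
kept.

Classification attaches a softmax head to the latent code: phase 1
pretrains the autoencoder unsupervised, phase 2 fine-tunes encoder + head
with cross-entropy (optional latent dropout).  This keeps the
reconstruction-driven compression of the fused 4,288-d feature vector while
producing the four-class posteriors the evaluation needs.

## Osprey optimizer

Internal convention is minimization; maximization is handled by negating
the objective.  Per iteration each member runs exploration then
exploitation, both greedily accepted (strict improvement only), with
candidates clipped to the box — so per-member and best-so-far fitness are
non-increasing by construction.  Two notational ambiguities in the update
rules were resolved as follows, with switches where reasonable:

* the exploration multiplier "rand[1, 2]" is read as a random **integer**
  I ∈ {1, 2} per dimension (the canonical form); a uniform-real-on-[1,2]
  variant is selectable (`i_mode="real"`);
* the exploitation divisor `k` is read as the current 1-based iteration
  counter `t`, giving the decaying step that local refinement needs.

Hyperparameter tuning searches latent dimension (8–64, integer), learning
rate (1e-4–1e-2), batch size (8–64, integer) and dropout (0–0.5).  The
fitness is macro-averaged precision `P = TP/(TP+FP)` on the validation
split — implemented exactly as that formula even though it is colloquially
called accuracy in parts of the optimization literature; a
`fitness_metric="accuracy"` switch selects plain accuracy.  Per-candidate
training uses reduced epochs, and candidate seeds derive deterministically
from (master seed, candidate index).  A candidate whose training fails is
scored worst-possible (0) with a warning and the search continues.

## Metrics

Per-class metrics use the one-vs-rest reduction of the 4×4 confusion matrix
(true classes on rows): accuracy (TP+TN)/n, precision, recall, F1, and AUC
from ranking the class posterior.  "Per-class accuracy" is deliberately the
one-vs-rest form, so it differs from overall accuracy and its macro mean
matches how averaged per-class tables are usually constructed.  A class
with no positive (or no negative) examples has undefined AUC; it is
excluded from the macro AUC with a warning.  Zero-denominator precision and
recall are reported as 0.

## Problem sizes and numerical choices

The test suite and the worked example run the full pipeline at a reduced
scale chosen as the smallest configuration that still exercises every
stage meaningfully: 12 patches per class at 64 px, 2 extractor epochs, an
osprey population of 2 for 2 iterations with 30-epoch candidate training,
and 40/80 reconstruction/fine-tuning epochs for the final model.  At this
scale an end-to-end run takes about a minute on one CPU and clearly beats
the 0.25 chance level.  Weights are float32 (gradient-check tests promote
to float64); capsule routing runs in float64 internally.  Routing logits
start at 0 (uniform couplings); softmax is max-shifted for stability;
`squash` and its Jacobian are guarded at the zero vector, where both vanish.

An optional checkpoint schedule evaluates the classifier on the test split
at chosen fine-tuning epochs within a single training run
(`AETrainConfig.checkpoints`), writing `metrics_epoch_<k>.json` per
checkpoint — one run with evaluations along the way, not independent
retrainings.

## Known limitations

* The synthetic textures are linearly separable by design; results on them
  bound nothing about real laryngoscopy data.
* Extractor training at desk scale is a few epochs on dozens of images —
  enough to test the machinery, far from convergence.
* The capsule layer's gradient detaches the couplings (see above).
* The numpy networks are single-threaded beyond BLAS; large-scale training
  is out of scope.
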