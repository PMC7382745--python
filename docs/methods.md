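# Methods

## Model

MDU-Net is an encoder–decoder segmentation network shared by four binary
tasks. The backbone has five encoder stages and four decoder stages; a
feature separation network of four per-task branches sits on the decoder
output.

**Encoder.** Stage 1 is a stem: a 3×3 convolution to `initial_channels`,
batch normalization, rectifier, at full resolution. Stages 2–5 each apply a
transition (1×1 convolution halving the channel count, batch norm, rectifier,
2×2 average pooling) followed by a dense block. Within a dense block of L
layers, layer k consumes the concatenation of the block input and all k−1
previous layer outputs and emits `growth_rate` channels, so the block widens
its input by L·`growth_rate`; each layer is a 3×3 convolution + batch norm +
rectifier. Four transitions give four 2× downsamplings; the bottleneck sits
at 1/16 of the input resolution. The full-scale profile mirrors the dense-201
layout (stem 64, growth 32, blocks [6, 12, 48, 32], input 512); a loader can
replace the encoder weights with a pretrained archive of exactly that layout
(all-or-nothing, with an explicit incompatibility error otherwise).

**Decoder and feature adaptation.** Each decoder stage upsamples 2× with a
kernel-2 stride-2 transposed convolution, concatenates the corresponding
encoder skip after a 1×1 feature-adaptation (FA) convolution, and applies two
3×3 convolution + batch norm + rectifier layers. The upsampling operator and
the decoder recipe are design choices (the canonical U-Net decoder); the FA
width per skip, `fa_channels`, is configurable and defaults to the channel
count of the encoder stage it adapts. Encoder skips are taken from the stem
and from each dense-block output except the deepest, which feeds the first
decoder.

**Feature separation branches.** Each task branch is two 3×3 convolution +
rectifier layers of width `branch_channels` and a 1×1 convolution to two
planes with a per-pixel softmax. The task order is fixed everywhere:
clavicle, anterior ribs, posterior ribs, all bones.

**Mask coding.** A binary mask is encoded as two complementary planes,
foreground "10" and background "01"; the network output is the per-pixel
probability pair (P1, P2) with P1 + P2 = 1, and decoding assigns foreground
iff P1 > P2. An exact tie decodes to background — the conservative choice for
clinical overlays; no threshold parameter exists anywhere in the path.
Converting the three structure masks to four independent two-plane targets
(the fourth being their union) turns the multilabel problem — pixels on both
an anterior and a posterior rib — into four single-label tasks; an overlap
pixel is simply foreground in both rib targets.

## Objective and metrics

The loss for task i is a categorical cross entropy between the predicted
probability pair and the encoded target, summed over the two categories and
averaged over batch *and* pixels; probabilities are clamped at 1e-7 before
the log. The printed form of the loss sums only over batch and categories;
averaging additionally over pixels keeps the magnitude independent of image
size and does not move the optimum. The total loss is the unweighted sum of
the four task losses, accumulated in fixed task order so the additivity
identity holds bit-exactly. No class weighting or Dice loss is used.

Evaluation metrics per (case, task): DSC = 2tp/(2tp+fp+fn), Jaccard =
tp/(tp+fp+fn), precision, recall, from pixel counts of the decoded mask
against truth. A case/task where prediction and truth are both empty scores
1.0 on all four metrics (an all-background task is a correct segmentation of
nothing; phantoms can produce such cases). Aggregates are per-image means and
sample (n−1) standard deviations over cases, never pooled pixels; a single
row has Std 0. Evaluation happens at the network's working resolution, not
resized back to the native size.

## Data pipeline

Cases are four 8-bit grayscale PNGs (`<case>_image/clavicle/anterior/
posterior.png`); masks are stored as {0, 255} and binarized at >127 on load.
Resizing uses bilinear interpolation for images and nearest neighbour for
masks (masks stay binary). The fourfold split shuffles ids once with the
given seed, takes the four consecutive equal blocks as test sets, and uses
the head of the remaining shuffled order for validation at the 10-of-66
proportion (with 88 cases: 22/10/56; other sizes divisible by four use
val = round(10/66·remaining), at least 1). Stratification is not used.

Online augmentation draws, per sample, a random affine transform — rotation
±10°, shift ±5 %, shear ±5°, zoom ±10 %, horizontal flip with p = 0.5 — and
applies the same geometry to image (bilinear) and masks (nearest), filling
out-of-frame pixels with 0. The ranges are typical for chest radiographs and
exposed in `AugmentConfig`. One epoch cycles the training cases
`expansion_factor` (default 10) times, so 56 cases yield 560 samples; the
stream is a pure function of (augmentation seed, epoch index).

## Training

One optimization run serves all four tasks (a quarter of the cost of four
single-task trainings). The optimizer is Adam (lr 1e-3 by default); epochs
default to 30 (desk profile) / 150 (full), batch 8 (desk) / 2 (full). After
each epoch the per-task validation mean DSC is computed by forward + argmax
decode + scoring; under the `per_task_best` policy a task's checkpoint is
overwritten when its validation DSC strictly improves, so the stored metric
is non-decreasing and all four checkpoints come from one trajectory (they
share a history id). "After each iteration" is realized as after each epoch —
per-batch checkpointing would thrash I/O — and "accuracy" as validation mean
DSC. The alternative `single_best_total` policy keeps the one model with the
lowest epoch training loss. Checkpoints bundle weights, batch-norm running
statistics, the full model configuration and best-metric metadata, so
evaluation and prediction need no side information. A run seed fixes weight
initialization (He fan-in for convolutions, unit/zero for batch norm),
sample shuffling and augmentation; two runs with the same configuration and
seed produce identical histories.

## Numerical engine

No autodiff library is part of the dependency set; the package carries its
own reverse-mode engine on numpy (`mdunet.autodiff`). Activations are
channels-last so im2col is a handful of contiguous copies feeding one BLAS
matmul per convolution; the patch-extraction kernels are JIT-compiled with
numba when available, with a pure-numpy reference path that tests assert
equal. Training runs in float32; every op preserves dtype so the test suite
gradient-checks in float64 against central finite differences. Batch
normalization uses batch moments during training (full backward through mean
and variance) and running estimates at inference, which makes inference
deterministic and batch-composition independent.

## The phantom generator

The generator emulates the statistical structure of the segmentation
problem, not thoracic anatomy: a smooth background with a vertical gradient
and a bright mediastinal column; two bright elliptical lung fields
(`lung_contrast`, default 0.7, scaling an additive 0.25); two near-horizontal
clavicle bands; and per side `n_rib_pairs` (default 5) posterior bands —
arcs of parabolas opening downward in image coordinates — crossed by the
same number of anterior bands opening upward. Vertex offsets and curvatures
are jittered per seed, but the two families' layout makes every
anterior/posterior pair cross inside the frame, so overlap pixels (the
multilabel phenomenon) exist for every seed. Band amplitudes (clavicle 0.35,
posterior 0.30, anterior 0.22 — anterior ribs are the faintest structure)
are attenuated by `outside_lung_attenuation` (default 0.5) outside the lung
ellipses, then the image is Gaussian-blurred (`edge_blur_sigma`, default 1.5
px) and corrupted with Gaussian noise (sd 0.02) and clipped to [0, 1]. Masks
record the exact band supports before blur and noise, so truth is crisp while
edges are fuzzy. Default size is 256×256 (desk scale; 1024×1024 supported).
Per-case seeds mix (root seed, index) splitmix-style, so datasets are
byte-reproducible without global random state.

What the phantom does *not* model: scapulae, heart and tracheal shadows,
vertebrae, exposure variation, anatomical shape statistics, or inter-case
correlation. Passing the generalization tests therefore shows the
implementation learns and separates overlapping band structures under noise
and contrast inhomogeneity — it does not certify clinical-radiograph
performance, which the private-data, GPU-scale protocol of the original
setting would require.

## Problem sizes and defaults in the shipped experiments

The desk profile (input 64, stem 8, growth 8, blocks [2, 2, 2, 2], branch
width 8, `fa_channels` defaulted to skip widths) trains in minutes on one
CPU. The shipped experiments use: an overfit run on a single phantom (120
epochs, lr 2e-3, identity augmentation — one case gives only two optimizer
steps per epoch, so memorization needs more epochs than the multi-case
default) reaching training loss < 0.01 and self-DSC 1.0; and a
generalization run with 58 phantoms (40 training / 8 validation / 10
held-out test, 30 epochs, default augmentation) reaching held-out mean DSC
around 0.93–0.97 per task. Full fourfold cross-validation over 88 cases is
supported (`cross_validate`, `mdunet cv`) and used at reduced epoch counts
in the test suite.

## Known limitations

* CPU-only: the full 512×512 dense-201 profile instantiates and runs
  forward, but training it is impractical without accelerator hardware.
* No real pretrained encoder weights are bundled; the loader is exercised
  with synthetic archives of the correct layout.
* The decoder recipe, FA widths, and branch architecture are reconstructions
  of design points the source description leaves open; all are configurable.
* Binary (foreground/background) tasks only; no multi-class encoding, soft
  labels, intensity augmentation, or test-time augmentation.
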