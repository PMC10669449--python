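# Methods

This note documents the model, the numerical choices behind it, and what
the synthetic validation does and does not demonstrate.

## Problem setting

Nondisplaced femoral-neck fractures appear on anterior–posterior pelvis
radiographs as thin (1–3 px at working resolution), low-contrast, slightly
curved dark lines inside the femoral neck. Two properties make them hard
for generic encoder–decoder segmenters: the signal is a *local orientation*
structure rather than a blob, and repeated down-sampling erases it. The
package addresses both with a direction-aware two-path encoder and a
two-phase pipeline that first isolates the femoral-neck region so the
detector operates at a favourable scale.

## The Gabor path

A Gabor wavelet is a Gaussian-windowed complex plane wave

    G(z) = (|k|²/σ²) · exp(−|k|²|z|²/(2σ²)) · (e^{i k·z} − e^{−σ²/2}),

with σ = 2π, wave-vector magnitude k_v = (π/2)/2^{v−1} (one octave per
scale step, v = 1..4) and angle φ_u = uπ/U, U = 8 orientations. The default
bank is 8 × 4 = 32 kernels; the layer output is the complex magnitude per
kernel, giving 32 real channels. The filter weights are fixed, never
learned — the direction/frequency selectivity is imposed analytically, and
the bank serializes as five numbers of metadata.

Discretization details that matter:

- **Zero mean.** The e^{−σ²/2} term cancels the DC response of the
  *continuous* filter only. On a truncated 15-px grid the residual DC is
  large (the envelope std σ/k_v = 4–32 px exceeds the window), so the
  sampled kernel is re-centred exactly: the quantity (ΣRe G / Σenv)·env is
  subtracted from the real part (the imaginary part sums to zero by odd
  symmetry). Every kernel's DC is then < 1e−6 of its L2 norm, and the bank
  ignores constant image regions. `make_gabor_kernel(..., dc_correct=False)`
  returns the raw analytic sample when the formula itself is needed.
- **Padding.** The Gabor layer uses edge-replicate padding so the band-pass
  property (zero response to a constant image) holds up to the border;
  learned convolutions use ordinary zero padding.
- **Response mode.** `magnitude` (default) is phase-invariant and maps
  8 orientations × 4 scales onto exactly 32 channels. It is positively
  homogeneous (response(aI) = a·response(I) for a > 0) but not additive;
  `real` and `real+imag` modes are linear in the image and available by
  configuration.
- **Orientation semantics.** Index u = 0 is a horizontal wave vector; a
  kernel responds most to lines *perpendicular* to its wave vector, exposed
  as `GaborBank.preferred_line_angle(u)`. Nearest-orientation ties break
  toward the lower index.
- **Kernel size.** Default 15 px. The v ≥ 3 envelopes are wider than this
  window, so coarse-scale kernels act as windowed plane waves; this is a
  deliberate cost/selectivity trade-off and is configurable.

## The ghost/SE path and attention

Ghost convolution spends a full convolution on only m = ⌈C·ratio⌉ of the C
output channels (ratio 1/2, 3×3 kernels) and derives the rest cheaply; at
ratio 1/2 this costs < 60% of the parameters of the plain convolution it
replaces. In the SE-ghost module the cheap branch is channel attention:
a squeeze-and-excitation gate (global average pool → bottleneck MLP with
reduction 4 → sigmoid) reweights the primary result per channel, and the
gated copy is concatenated with the primary result. Batch normalization and
a rectifier follow the primary convolution.

The attention block on the decoder path applies channel gating (SE) and
then a spatial gate — a sigmoid of a 7×7 convolution over the channel-mean
map. Both gates lie in (0,1), so attention only attenuates; forcing both
gates to 1 recovers the identity (a property the tests exercise through the
`gate_override` hook).

## Architecture

Three encoder stages at full/half/quarter resolution. Stage widths at the
default configuration:

| tensor | channels (1024-px input) |
|--------|--------------------------|
| Gab1–3 | 32 / 32 / 32 |
| GhoM1–3 | 32 / 64 / 128 |
| GG1–3 (concat) | 64 / 96 / 160 |
| PF1–3 | 32 / 64 / 128 |
| A1–3 | 64 / 128 / 256 |
| output | 1 |

The ghost path chains SE-ghost modules separated by 2×2 average pooling;
the Gabor path is computed once at full resolution and average-pooled to
the lower stages (it depends only on the input, so training computes it
once per dataset). Per stage, the concatenation GG_i is refined by 2×2
average pool → 3×3 convolution → batch norm → rectifier → 2× nearest
upsample back to stage resolution (PF_i), re-joined with the ghost features
and passed through attention (A_i). The decoder 2×-upsamples the deepest
attention map, concatenates with the next shallower one, and fuses with a
3×3 convolution down to that stage's ghost width; a terminal 1×1
convolution and sigmoid emit the probability map at input resolution.

Choices the stage table does not fix, made here: the down-sampling operator
is average pooling everywhere (the refinement path names it; the encoder's
operator is unspecified and the same one is used for consistency);
up-sampling is nearest-neighbour (a fixed 3×3 smoothing kernel approximates
bilinear as a config option); decoder fusion widths follow the encoder's
ghost widths; the output activation is a sigmoid so the mean-squared-error
regression target (a binary mask) and the probability-map contract coexist.
One stage-table entry is internally inconsistent — the third concatenation
is printed as 150 channels where its inputs sum to 32 + 128 = 160 — and the
implementation produces 160.

The output head's bias initializes at −3 rather than 0: fracture masks are
a ~1% pixel minority, and a sigmoid opening near the class prior spares MSE
optimization the long traverse of the saturated region. `train()`
re-initializes the bias to the logit of the actual label mean
(`TrainConfig.prior_bias_init`, on by default) — measurably decisive for
the ROI stage, whose foreground fraction is ~30%.

## Training

Mean-squared error between the probability map and the binary mask,
optimized with Adam under a stepped warm-up: learning rate 1e−5 at epoch 0,
+1e−5 per epoch, capped at 4e−5 (the step granularity is per-epoch; at this
step count the distinction from per-iteration stepping is immaterial).
Batches of 12 by default, drawn by seeded shuffling. When a validation set
is supplied, training stops after 20 epochs without improvement. Everything
is reproducible from (model seed, data, config): the engine is pure
float32 numpy, so repeated forward passes are bit-identical.

The two pipeline stages are trained independently on their own labels
(femoral-neck masks for stage 1, fracture-line masks for stage 2), sharing
the same architecture.

## The implementation substrate

The network runs on a minimal reverse-mode autodiff engine written for this
package (`dafdnet.autodiff`): tensors wrap float32 numpy arrays, 2-D
convolution is im2col + BLAS matmul, and every layer's analytic gradient is
verified against central differences in the test suite. Spatial convolution
is used throughout (no FFT path). This keeps the dependency surface at
numpy/scipy and makes desk-scale experiments deterministic.

## Two-phase pipeline

Stage 1 thresholds the ROI probability map at 0.5, keeps the largest
8-connected component (ties broken toward the top-left component), pads its
bounding box by 10% per side, and resamples the region into the detection
network's input square — uniform scale on the longer side, aspect
preserved, centred with mean-intensity padding. Stage 2 segments the crop
and post-processes the same way. The crop transform (box, scale, pads) is
recorded exactly; detected boxes map back to full-image coordinates within
one pixel per corner for upscaling crops (region not larger than the crop
square — the operating regime, since localization exists precisely to hand
the detector a smaller region). Empty threshold outputs yield explicit
"no ROI"/"no fracture" flags, never exceptions; the map's maximum
probability is always reported.

## Evaluation metrics

IOU is computed on axis-aligned bounding rectangles (half-open pixel
semantics), Dice and Jaccard on pixel masks; J = D/(2−D) links the two, and
the box/mask distinction is why the two families differ numerically on
elongated structures. Conventions pinned by tests: both masks empty → Dice
= Jaccard = 1; exactly one empty → 0; IOU bins at {0.2, 0.5} are
lower-inclusive (0.5 falls in the top bin); summaries are emitted on the
percentage scale.

## The phantom generator

Each phantom is: a smooth background texture (Gaussian random field,
correlation length image_size/8, level 0.35 ± 0.06), a brighter ellipse
standing in for the femoral neck (+0.2 with a softened rim; semi-axes
26–32% and 15–20% of the image side), a dark quadratic-Bézier crack through
the ellipse centre at a random orientation (length 1.5× the ellipse radius
along that direction, bow up to 12% of its length, nominal width 1–3 px,
peak contrast drawn from 0.03–0.10), and white noise (sd 0.01). The crack
mask is clipped to the ellipse, so the ROI always contains the fracture.
Rendering is bit-reproducible from the seed.

Augmentation applies one transform — rotation uniform in ±15° composed
with a fixed 0.95 rescale about the centre — identically to the image and
both masks (bilinear for the image, bilinear + 0.5-threshold for masks),
eight variants per base image by default. Dataset assembly splits at the
base-image level, so no augmented sibling of a training image can appear in
the test set; the default train share 375/480 of bases reproduces a
3000/840 image split at eight variants.

What the phantoms emulate: the figure–ground contrast regime (thin dark
curve inside a brighter convex region on a textured background), the
orientation randomness of fracture lines, and sensor noise. What they do
not: real anatomy (trabecular texture, cortical edges, overlapping pelvic
structures), scanner physics (scatter, heel effect, dose variation), or the
intensity statistics of any clinical archive. Passing the synthetic
learning checks therefore demonstrates that the implementation can learn
and localize thin oriented structures end-to-end — not any level of
clinical performance.

## Problem sizes and tolerances used in validation

Architecture conformance and the reported channel counts are probed at a
128-px input (channel counts are independent of spatial size, which is
itself a pinned property). The learning sanity runs use the reduced
configuration (input 128, stage widths 8/16/32, Gabor scales {1,2}) with
64 training and 32 test phantoms at crack width 3 and contrast 0.08–0.15,
Adam at constant 2e−3 — conditions under which the task is
solvable-but-nontrivial on one CPU in minutes. The augmentation/count check
runs the full 480-base, 8-variant dataset at 256 px. Gradient checks accept
2% relative error against central differences (float32 arithmetic); the
orientation-rotation equivariance check allows 5% on mean channel
responses, dominated by interpolation and kernel discretization.

## Known limitations

- The magnitude response is non-linear (phase-invariant by design); use
  `real` mode where linearity in the image matters.
- Coarse Gabor scales are window-limited at the default 15-px kernel.
- MSE treats false positives and misses symmetrically; on extremely sparse
  targets a region loss would likely converge faster — out of scope here
  because the objective is part of the method being implemented.
- The early-stopping criterion does not restore best-epoch weights; the
  history makes the best epoch recoverable.
- Discrete orientation channels have slightly unequal gains (truncation
  anisotropy); comparisons across orientations are reliable at the ~2%
  level on smooth images, well inside the 5% test band.
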