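# Methods

## The model

`pestseg` implements binary pest-versus-background segmentation with a
U-Net whose feature blocks and skip connections are modified in two
ways.

**Dilated multi-scale (Inception-style) blocks.** Instead of the plain
double 3×3 convolution of U-Net, each encoder/decoder stage applies a
four-path block. Three branches apply a 1×1 bottleneck (to `b`
channels) followed by a 3×3 convolution dilated at rates r = 1, 2, 3.
A dilated kernel samples its input at offsets r·i, equivalent to
convolving with a kernel zero-inflated to edge
k_s = k + (k−1)(r−1); it covers a k_s×k_s footprint with the original
k² weights, growing the receptive field by (k_s/k)² at constant
parameter cost. The three branches therefore see 3×3, 5×5 and 7×7
footprints simultaneously — matched to pests whose areas span more
than an order of magnitude. A fourth path global-average-pools the
input, applies a 1×1 convolution and bilinearly upsamples back,
injecting image-level context that the independent branches lack. All
paths plus the raw input (a residual route) are concatenated along
channels and fused by a 1×1 convolution. The block *reduces* parameter
count relative to a double-3×3 block at equal width, because the 3×3
work happens at bottleneck width; this is a deliberate property, not an
accident (the cheap multi-scale coverage is the point). An additive
fusion mode (`fusion="add"`) sums the paths instead; it exists for
comparison and is not the default.

The ablation variant `unet_inception` swaps the branch geometry for the
classic multi-kernel form — 1×1, 3×3 and 5×5 kernels, no dilation —
so the dilation-versus-kernel-size distinction can be measured; the
strictly-increasing-footprint rule (1 < 3 < 5, or 3 < 5 < 7) is what
the block's config validates.

**Channel-attention gates on skips.** Before an encoder skip is
concatenated into the decoder, its per-channel global max and mean
descriptors pass through a shared two-layer MLP (C → C/ρ → C, ReLU in
the middle; the weights are shared between the max and mean branches),
the two excitations are summed, and a sigmoid produces per-channel
weights S_a ∈ (0,1) that rescale the skip map. The gate can only
attenuate (‖gated‖∞ ≤ ‖input‖∞); its role is to suppress channels that
carry background texture before they pollute the decoder. The
reduction ρ defaults to 8; at narrow stage widths the model uses the
largest divisor of C not exceeding ρ so the hidden layer never
vanishes.

The encoder halves resolution with 2×2 max pooling and doubles width
per stage (widths base·2^s, bridge capped at the deepest stage width);
the decoder upsamples bilinearly (avoiding deconvolution checkerboard
artifacts) and restores channels with a 1×1 convolution; a 1×1
convolution + sigmoid head emits the per-pixel foreground probability.
Six named variants (`unet`, `unet_attn`, `unet_inception`,
`unet_dilated_ms`, `unet_inception_attn`, `dmsaunet`) toggle the block
type and the gates so each component's contribution is measurable.

## Objective and metrics

Training minimises `total_loss = iou_loss + bce_loss`:

* soft Jaccard: 1 − Σ(w·p·t) / Σ(w·(p+t−p·t)) — a global, region-level
  supervision signal in [0,1];
* weighted mean binary cross-entropy with predictions clipped to
  [1e−7, 1−1e−7] — a local, per-pixel signal.

The per-pixel weights w default to 1. An optional boundary-emphasis
mode sets w = 1 + λ·|mean3×3(t) − t| (λ = 5), concentrating weight in a
ring around object edges; it exists because edge quality is the usual
failure mode, but the uniform default is what all reported numbers use.
A pure-BCE mode (`loss_mode="bce"`) is selectable since plain
cross-entropy is a common protocol for this task family.

Evaluation thresholds the probability map at 0.5 and pools pixel
confusion counts. `accuracy` is deliberately the recall form
TP/(TP+FN) — the convention this model family is reported with — and
`iou` is TP/(TP+FP+FN); the conventional (TP+TN)/total is exposed as
`pixel_accuracy` under its own name and never silently substituted.
Micro (pixel-pooled) aggregation is the default; per-image means are
reported alongside.

## Numerical implementation

No deep-learning framework is used: the package carries a minimal
reverse-mode autodiff tape (`pestseg._tensor`) over float64 numpy
arrays, implementing exactly the operators the model needs (dilated
same-padding convolution as a k² tap loop over BLAS matmuls, 2×2 max
pooling with first-maximum tie-breaking, separable bilinear resampling
via explicit interpolation matrices with half-pixel centres and edge
clamping, global pooling, dense layers, elementwise ops). Every
backward pass is verified against central finite differences in the
test suite; the whole-model gradient was spot-verified the same way.
Weights are He-uniform, biases zero, all drawn from a generator seeded
by the run seed, so a (config, seed) pair fixes every reported number
bitwise. The optimizer is Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−8) at a
constant learning rate of 1e−3; "iterations" are optimizer steps, not
epochs; there is no schedule and no early stopping. Augmentation
(random flips and square 90° rotations, drawn from the run's generator
so seeded runs stay exactly reproducible) exists behind
`TrainConfig(augment=True)` and is off by default.

## Synthetic data

The generator emulates the difficulty axes of field pest photographs —
shape, pose, size, colour, illumination, background clutter — with
fully controlled renders:

* pests: rotated ellipses (semi-axis a uniform-fraction of the image
  diagonal, aspect U(0.5,1)) whose boundary radius is perturbed by
  zero-mean sinusoidal harmonics (orders 2–4) scaled by
  `shape_irregularity`, drawn in dark insect colours with low-frequency
  body shading; pests never touch (a 2-pixel gap is enforced), so the
  mask is the exact disjoint union of their supports and component
  counts equal blob counts;
* background: a green-palette base modulated by low-frequency value
  noise and high-frequency grain (foliage-like, not photorealistic);
* illumination: a linear brightness ramp in a random direction with
  total swing `illumination_gradient`;
* clutter: background-coloured speckles that are deliberately absent
  from the mask — distractors the segmenter must ignore;
* pixel noise: additive Gaussian, σ = 0.02 by default.

Every sample is a pure function of (seed, index) via spawned numpy
`SeedSequence`s. Default blob scales (0.04–0.14 of the diagonal) give
blob areas spanning ≥ 10×, which is what makes the multi-scale blocks
relevant; the analytic expected foreground fraction
E[k]·π·E[s²]·D²·E[aspect]/(H·W) is exact up to the ~2–4% area inflation
of the boundary perturbation and is used as a Monte-Carlo check.

What the generator does *not* emulate: real texture statistics of
insects and foliage, occlusion, motion blur, compression artifacts, and
class taxonomy (it is binary by design, matching the model head). Tests
passing on this data show the pipeline is correct and that the
architectural components help on controlled multi-scale data; they do
not certify field performance.

## Desk-scale study sizes

Full-scale training (128×128 inputs, base width 64, thousands of
iterations over thousands of images) is GPU-scale. The package's two
reference studies (`pestseg.studies`) are fixed at sizes where a full
run completes in minutes on one CPU core:

* **overfit study** — 12 synthetic images at 64×64, `dmsaunet` with
  depth 3 / base width 8, batch 6, 450 Adam steps. Converged reference
  behaviour: training IoU ≈ 0.97 (threshold: ≥ 0.90) and the median
  mini-batch loss over the last tenth of steps far below the first
  tenth (≈ 0.05 vs ≈ 1.2).
* **ablation study** — 30 synthetic images at 32×32, 5-fold CV with
  shared folds, depth 2 / base width 4 (branch bottlenecks pinned at 4
  channels so the multi-scale block is not starved at this width),
  batch 4, 850 Adam steps per fold, repeated over three seeds; compares
  `unet` against `dmsaunet` mean test IoU. At narrow desk-scale widths
  and small data the margin between variants is inherently noisy; the
  study checks the *direction* (the full variant does not lose), not an
  effect size.

## Degenerate inputs and tie-breaks

Empty union in the IoU loss (both maps all-zero) is defined as loss 0
with a warning. Max pooling and global max pooling route gradients to
the first maximum on ties. Constant images make fuzzy c-means
degenerate: it warns and returns an empty foreground rather than an
arbitrary split. FCM initialises centroids at evenly spaced intensity
quantiles (deterministic, no seed needed), iterates membership/centroid
updates (fuzzifier m = 2, tol 1e−5 on centroid shift, ≤ 100 iterations,
warning on non-convergence), and labels the cluster whose intensity
centroid lies farthest from the histogram mode of intensity as pest —
a heuristic that visibly fails under strong illumination gradients,
which is the instructive property of the baseline.

## Known limitations

* CPU-only and float64: a training step at full scale (128×128, base
  64) is far slower than any framework implementation; the package is
  built for correctness, inspectability and exact reproducibility, not
  throughput.
* The attention gate is purely channel-wise (global pooling → MLP →
  per-channel sigmoid); no spatial attention map is computed.
* The synthetic generator's realism limits are listed above; no loader
  for external pest datasets beyond the generic PNG/TIFF manifest
  reader is included.
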