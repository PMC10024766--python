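# Methods

`litesal` implements a lightweight salient-object-detection (SOD) network
for locating bone regions in livestock X-ray images, together with the
saliency evaluation protocol, a CPU training loop and a synthetic scene
generator. This note records the model, the choices that were genuinely
open, the numerical conventions, and what the synthetic experiments do and
do not demonstrate.

## The network

The detector is an encoder–decoder with a residual refinement tail. Input
and output are 224×224; the output is a single-channel saliency map in
[0, 1] whose high values mark the bone (or, on generic scenes, the salient
object).

**Encoder.** Five stages, each a stride-2 3×3 conv–BN–ReLU entry followed
by optional same-width blocks and a multiscale attention module (MAM).
Widths grow deliberately slowly — 16, 32, 64, 96, 128 — ending at a
7×7×128 feature map; avoiding exponential channel growth is what keeps the
parameter count at 2.1 M.

**Multiscale attention module.** Each stage output `I` passes a shared
conv–BN–ReLU, then three dilated-conv branches evaluated at 2×, 1× and
0.5× spatial scale (dilations 1, 2, 4; bilinear resize up, adaptive
average-pool down, everything resized back to 1×). The branch outputs
F₁..F₃ are summed into `F`; per branch, a channel-attention head (global
average pool → bottleneck MLP, reduction 4 → sigmoid) and a spatial-
attention head (channel mean+max → 3×3 conv → sigmoid) score `F`, their
product forms a per-pixel-per-channel logit, and a softmax **across the
three branches** yields weights S₁..S₃ that select among scales. The
module returns `fuse(ΣFᵢSᵢ) ⊕ I` with a 3×3 conv–BN fuse and a residual
add, so a zeroed module is exactly the identity. The per-branch attention
heads are this package's resolution of an ambiguity: a single attention
map cannot be softmaxed across branches, so each branch gets its own heads
over the shared fused feature.

The 0.5× branch floor-halves the resolution, so the module accepts odd
sizes (the terminal stage runs at 7×7); only single-pixel axes are
rejected.

**Decoder.** The deepest feature first passes a pyramid pooler (bins
1, 2, 3, 6; per-bin 1×1 conv to 32 channels; concatenate with the input;
1×1 conv–BN–ReLU back to 128) giving `P`. Four full-scale skip stages then
run coarse to fine at 14/28/56/112 resolution with widths 96/64/32/16
(mirroring the encoder). Stage i concatenates four sources — the wiring
table in `litesal.decoder` lists them; every shallow encoder stage feeds
the decoder and `P` reaches every stage — after reducing each to a quarter
of the stage width (1×1 conv) and resizing to the stage resolution. A 3×3
conv–BN–ReLU fuses the concatenation, and the carried feature (`P` for the
first stage, the previous decoder stage otherwise) is added residually
after its own resize + 1×1 projection. Quarter-width reduction keeps the
concatenated width exactly equal to the stage width — the anti-explosion
constraint. A 3×3 conv head on the finest stage plus a 2× bilinear
upsample produces the 224×224 coarse logit map.

**Refiner.** A five-stage conv encoder over the coarse probability map
(filters 4, 8, 16, 24, 36, all 3×3 conv–BN–ReLU, 2×2 max pool between
stages) and a mirrored five-stage decoder (bilinear upsampling, filters
36, 24, 16, 8, 4) ending in a 3×3 conv to one channel. The printed filter
schedule names five numbers for "encoder and decoder"; mirroring it for
the decoder is the minimal symmetric reading and adds only ~13 k
parameters. The residual is added to the coarse map **in logit space**
with a single final sigmoid: adding probabilities directly can leave
[0, 1], whereas `sigmoid(logit_coarse + residual)` is bounded by
construction and reduces exactly to the coarse map when the refiner is
zero. The refiner sees only the coarse map (one channel), not the image.

**Parameter budget.** Widths are fixed as above; the per-stage block count
is the depth knob. `blocks_per_stage = [1, 1, 1, 2, 2]` gives 2,117,651
trainable scalars, i.e. 2.1 M at one decimal. The count is recomputed at
runtime (`count_parameters`), never stored.

## Numerical conventions

Tensors are NCHW float32. All resampling is bilinear with
`align_corners=False`, implemented as separable interpolation matrices
(the backward pass is the transposed product); adaptive average pooling
uses floor/ceil bin edges. Convolutions are zero-padded
(`pad = dilation`), evaluated as one GEMM over an im2col column tensor.
Batch norm uses per-batch statistics in training and running statistics
(momentum 0.1, eps 1e-5) in eval; variances are biased (1/N). Weights are
Kaiming-uniform from a `numpy` generator seeded by `ModelConfig.seed`, so
model construction, forward passes and training are bit-reproducible.
Cross-entropy clamps probabilities to [1e-6, 1−1e-6]; the clamp zeroes the
gradient at saturated pixels instead of producing infinities. The branch
softmax subtracts the (detached) running maximum before exponentiation.

The package carries its own small reverse-mode autodiff tape
(`litesal.nn`): the network needs only a closed set of operations, and
owning them keeps the dependency surface to numpy/scipy while making every
backward rule unit-testable against finite differences. The tape is
single-shot: gradients and parent links are released as each node's
backward runs, which keeps a full 224×224 training step within ~1.5 GB.

## Training recipe

Adam (β = 0.9/0.999, no weight decay), initial learning rate 3e-4, cosine
annealing `lr0 · 0.5 (1 + cos(π·epoch/epochs))` stepped per epoch with
floor 0, 60 epochs by default, paired horizontal flips with probability
0.5. The loss is plain BCE on both the coarse and refined maps with equal
weights — the recipe's published parts fix the optimizer and schedule but
not the loss; BCE is the simplest choice consistent with sigmoid outputs,
and a BCE+soft-IoU hybrid is available behind `TrainConfig.hybrid_iou`.
Batch size is unpublished; the default is 16, and the desk-scale
learnability check uses 4 so that 16 images × 50 epochs align exactly with
a 200-step budget and one full annealing cycle.

## Evaluation protocol

* **MAE** — mean absolute pixel difference.
* **max-F** — F with β² = 0.3 maximized over 256 evenly spaced strict
  (`p > t`) thresholds. β² = 0.3 is the SOD convention; some papers print
  0.03 and `MetricConfig.beta2_f` reaches it. An adaptive-threshold
  variant (t = 2·mean) sits behind a flag.
* **weighted F (Fωβ)** — β² = 1; the error map is substituted on the
  background by the error at the nearest foreground pixel, smoothed with a
  7×7 Gaussian (σ = 5) where that lowers foreground error, and discounted
  on the background by `2 − exp(ln(0.5)/5 · Δ)` with Δ the Euclidean
  distance to the foreground. These constants follow the established
  weighted-F protocol and are exposed in `MetricConfig`.

Masks load as foreground at gray ≥ 128 (benchmark masks are
anti-aliased); predictions load from 8-bit PNGs, so round trips through
disk carry a ≤ 1/255 quantization error that the tests account for.
Whether published benchmark numbers used continuous or saturated maps is
not recoverable; this package scores the continuous maps it writes.

## Synthetic data

The generator exists so the whole pipeline is testable offline; it is a
statistical stand-in, not a physical simulation.

* **blob** scenes: 1–3 smooth bright shapes (ellipses / radial-Fourier
  blobs, possibly clipped by the border) over gaussian-filtered texture.
  At `contrast=1, noise=0` an Otsu threshold recovers ≥ 99 % of the mask —
  the label-consistency oracle.
* **xray** scenes: dark field; a soft-tissue region bounded by a smooth
  random closed contour; inside it, a spline-tube "bone" (radius ≈ 3 % of
  the image side, wobbled, optionally branched) raised `contrast` (default
  0.15) above the tissue, plus gaussian sensor noise (default σ = 0.02).
  The mask is the exact tube; bone-pixel fraction averages ≈ 0.06 over
  many draws. Real radiographs add beam hardening, scatter, overlapping
  anatomy and annotation ambiguity — none of which are modelled — so
  passing the synthetic learnability check demonstrates optimization and
  representation capacity, not clinical-grade segmentation.

Every sample is a pure function of the seed (per-image child seeds from a
`SeedSequence`), down to the bytes of the written PNGs.

## Problem sizes in the test suite

The suite verifies forward blocks against quadruple-loop oracles on ≤ 6×6
tensors (1e-5), gradients against central differences on ~50-element
tensors, the weighted-F implementation against a dense per-pixel oracle on
5×5 fixtures (1e-9), and learnability by overfitting 16 scenes for at most
200 optimizer steps to training MAE < 0.05 — sizes chosen so the whole
suite runs in minutes on one CPU core.

## Known limitations

No GPU path and no pretrained backbone; the encoder trains from scratch.
Benchmark-scale accuracy claims are out of scope — they would require the
original training corpus and multi-day training. The refiner is single
pass (no cascaded refinement), and no boundary-specific loss is used. The
synthetic X-ray generator's mask semantics (exact tube) is a declared
convention, not a reproduction of any annotation protocol.
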