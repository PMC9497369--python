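# Methods

## Scope and numerical core

The package implements a parallel CNN–transformer encoder–decoder for
binary segmentation of 2-D brain slices, its hybrid training objective, the
five-metric evaluation suite, and a phantom generator. All computation runs
on a small reverse-mode autodiff engine written for this package
(`rmtfnet.autograd`): float64 NumPy tensors with hand-derived backward
rules for each primitive. Float64 was chosen over float32 because the test
suite validates the attention mechanism and the SSIM computation against
independent brute-force oracles at 1e-5/1e-6 tolerances; the speed cost is
irrelevant at the problem sizes used here. Every backward rule is checked
against central finite differences in the test suite.

Convolution is computed as a sum over kernel offsets of strided views
(efficient for the 1×1/3×3/7×7 kernels used), and bilinear resizing as an
exact separable linear map built from 1-D interpolation matrices with the
half-pixel-center convention — which is why constants are preserved exactly
and the adjoint (backward) is just the transposed matrices.

## Encoder

**Stage hyperparameters.** The mix-transformer family is parameterized per
stage by patch (K, S, P), embedding dim, depth, heads, and reduction R.
Defaults are the published "B"-family values: dims (64, 128, 320, 512),
depths (3, 4, 6, 3), heads (1, 2, 5, 8), MLP ratio 4, patches (7, 4, 3)
then (3, 2, 1)×3, and R = (64, 16, 4, 1) — so the spatial-reduction strides
(8, 4, 2, 1) exactly cover each stage's grid. The "L" variant deepens the
third stage to 40 blocks, the deepest published scaling of this family;
since no other parameterization is fixed anywhere, B vs L differ only in
depth here.

**Sequence reduction.** Shortening N tokens to N/R by "reshape to N/R
tokens of dimension C·R, then a linear layer back to C" is implemented as a
convolution with kernel = stride = √R over the token grid followed by layer
normalization: the same linear map on R-pixel blocks, without reshape
bookkeeping. For R = 1 the module reduces to ordinary full attention, which
is what the quadratic-oracle test exploits.

**Mix-FFN residual placement.** The residual is placed *outside* the MLP:
`x + MLP(GELU(Conv3×3(MLP(x))))`. Written with the residual inside the
outer MLP's argument the block could not reduce to the identity at zero
weights; the outside placement matches the construction this block
originates from. Blocks are pre-norm (LayerNorm before attention and FFN),
the standard stable choice for this encoder family; normalization layers
also follow each patch embedding.

**Initialization.** Truncated normal (σ = 0.02, resampled beyond 2σ) for
linear weights, fan-out-scaled normal for convolutions, zeros for biases —
all drawn from one seeded generator threaded through the model constructor,
so a model built twice from the same seed is bitwise identical.

## Fusion branch

The residual branch uses a 7×7 stride-2 stem and four stride-2 residual
blocks with channels (64, 128, 256, 512); only the resolutions of the fused
maps are constrained by the architecture, not the stem, so the stem is the
minimal choice that makes block *i* consume features at the resolution of
the ×2-upsampled pyramid map M_i. Upsampling is bilinear with no learnable
parameters. Concatenation order is frozen as (running feature, transformer
feature). A residual block uses a projection shortcut (1×1 conv + BN)
exactly when channels or resolution change.

## Decoder

GFI needs X and C at equal channel counts for the addition; C is projected
by a 1×1 convolution when they differ, and the projected C is also the one
concatenated, keeping the module's channel arithmetic self-consistent. X is
the transformer map and C the CNN map, so the skip carries the global
attention feature and GFI's output channels track the pyramid dims. GFI is
applied at all four scales; the deepest output is the decoder input rather
than a skip. Decoder channels halve (256, 128, 64, 32). Four ×2 decoder
blocks climb from 1/32 to 1/2 resolution; since four doublings cannot reach
full resolution from 1/32, the head performs its 7×7 convolution at 1/2
resolution and then upsamples ×2 — putting the convolution before the
upsample keeps the head cheap and the logits smooth. Binary masks are
obtained by sigmoid + 0.5 threshold.

Ablation variants are structural switches on one implementation: `backbone`
(no GFI, Dice-only loss), `w_gfi`, `w_hloss`, `mit_only` (decoder fed by
the pyramid maps), `rcnn_only` (fusion concatenation disabled). `w_hloss`
is parameter-identical to `backbone`, differing only in the objective.

## Losses

The trainable Dice term is 1 − coefficient, with the coefficient
(2Σtᵢeᵢ + ε)/(Σtᵢ + Σeᵢ + ε), ε = 1e-6; minimizing the raw coefficient
would minimize overlap. BCE clamps probabilities to [1e-7, 1 − 1e-7]. SSIM
uses the standard parameterization — 11×11 Gaussian window, σ = 1.5,
C1 = (0.01L)², C2 = (0.03L)², dynamic range L = 1 for probability maps —
over *valid* windows, so the windowed statistics need no padding
convention and the brute-force sliding-window oracle is unambiguous. SSIM
is computed on the probability map, not the thresholded mask, because the
loss must stay differentiable. Default weights α = β = γ = 1; no weighting
is fixed anywhere, so they are explicit and configurable.

## Metrics

wFm, Em and Sm are implemented in their canonical published constructions
(the definitions the segmentation-benchmark community shares): wFm with
distance-transform-based error redistribution (7×7 Gaussian σ = 5 diffusion
inside the object, exponential distance penalty 2 − exp(ln(0.5)/5·D)
outside, β² = 1); Em with bias-removed alignment enhanced quadratically;
Sm = 0.5·S_object + 0.5·S_region with the region term computed on the four
quadrants about the foreground centroid. Dice/IoU/Em binarize predictions
at 0.5; wFm and Sm consume soft maps, matching each metric's native
definition. Em on binarized maps is the common convention. Degenerate
tumor-free slices: empty truth + empty prediction scores 1 on all metrics,
empty truth + nonempty prediction scores 0, except Sm which keeps its
published rule (1 − mean prediction). Em and Sm are clipped to [0, 1] (the
published Em normalizer divides by N−1, which exceeds 1 marginally for
perfect agreement).

## Phantom generator

Each phantom is an elliptical "brain" field (radial intensity falloff plus
Gaussian-smoothed low-frequency texture) with additive Gaussian noise
(σ = 0.03), replicated to 3 channels and clipped to [0, 1]. With
probability 0.9 a lesion is added: a base ellipse with 2–5 smaller
protruding lobes anchored on its boundary, intersected with the brain,
rendered ~0.35 brighter with a 1-pixel-smoothed edge. The lesion's area
fraction is driven into a configurable band (default 1–12 % of the image)
by multiplicative radius correction with rejection, so lesion sizes are
controlled without biasing shapes. The exact binary mask is returned; the
rendered brightness uses a slightly smoothed copy, so edges in the *image*
are soft while the *label* stays crisp — emulating the partial-volume look
of real slices.

What the phantoms do **not** emulate: multi-modal MRI contrast, anatomy
(ventricles, skull, bias fields), infiltrative low-contrast tumor margins,
or inter-slice correlation. Passing the overfit and metric tests therefore
demonstrates that the architecture, gradients, losses and metrics are
correct and that the model can fit irregular bright lesions — not that it
reaches any particular accuracy on clinical data.

## Training harness

Adam with learning rate 1e-4 and weight decay 1e-5, batch size 18, inputs
at 256×256 and 30 epochs are the full-scale defaults. The `tiny()`
configuration (embedding dims ÷8, depth 1 per stage, CNN channels
(8, 16, 32, 64), decoder (32, 16, 8, 4), 64×64 inputs, batch 4) uses
learning rate 1e-3: the scaled-down network and images support a larger
step, and the point of the tiny variant is rapid memorization on a CPU. No
learning-rate schedule, augmentation or early stopping is used anywhere;
flags for them are deliberately absent rather than silently defaulted.
Runs are fully seeded (phantoms, initialization, shuffling, splits);
training aborts with a diagnostic on a non-finite loss. The best-validation
checkpoint is kept; with `val_fraction = 0` the training set doubles as the
validation set, which is the intended setting for overfit-capacity checks.

## Problem sizes

The test suite and the acceptance script train the tiny variant on eight
64×64 phantoms for at most 300 steps (about a minute on one CPU) and run
the full-size variant-B network forward once at 256×256 (a few seconds).
These sizes are chosen so that correctness properties — oracle equivalence,
resolution contracts, descent, memorization, bitwise reproducibility — are
decisive while the whole suite stays in the minutes range.

## Known limitations

- Single-class (whole-tumor) output only; no multi-class heads.
- No pretrained backbone weights; all training is from scratch.
- The autodiff engine materializes the full graph per step; it is sized for
  the tiny variant's training and the full variant's inference, not for
  full-scale training, which would need a GPU framework.
- BatchNorm running statistics make train-mode and eval-mode outputs
  differ, as usual; all reported metrics use eval mode.
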