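# Methods

This note documents the model as implemented, the choices made where the
architecture description left the design open, the synthetic data the
tests run on, and what passing those tests does and does not establish.

## Architecture

**Branches and pyramid.** The conv branch is a self-contained residual
stack: a two-conv stem to H/4, then three stages of two 3×3 residual
blocks (BatchNorm + ReLU, 1×1 projection shortcut on shape change),
channels (C1, C2, C3), stride 2 between stages, each stage ending in an SE
block and a global average pool. No pretrained backbone is loaded: all
weights are He-normal initialized from a single seeded generator, which
makes rebuilds bitwise reproducible and keeps the package free of
downloads. The attention branch patch-embeds the raw image (4×4 patches,
dim D) — not the conv features; the two branches are parallel entries that
meet only at the fusion sites. Three windowed-attention levels at dims
(D, 2D, 4D) with depths (2, 2, 2) and heads (3, 6, 12) follow, patch
merging between levels; level 3 has no merge. The fused tokens entering
level 1 serve as S1, and level 3's output is S3.

**Attention details.** Blocks are pre-norm (LN before attention and MLP),
MLP ratio 4, GELU. Window attention alternates shift 0 and ⌊M/2⌋; the
shifted variant is a cyclic shift plus additive mask that forbids
attention between tokens that were not spatial neighbours before the
shift. Grids not divisible by M are zero-padded bottom/right and cropped
after; padded tokens are isolated by the same mask. The
relative-position bias is the additive row+column decomposition
`B[i,j] = Er[Δr+M−1] + Ec[Δc+M−1]`, one (Er, Ec) pair per attention
layer shared across heads, always added *inside* the softmax logits (the
only dimensionally coherent reading). Head dim is model-dim / heads.

**Stage-exit normalization.** The pre-norm residual stream is unbounded —
empirically its scale grows to O(10) std by level 3 — so each attention
level applies a LayerNorm after its blocks, before SE recalibration and
merging. Without it the downstream cross-attention logits saturate and
the decoder receives spatially near-constant features; with it the
whole model trains. Hierarchical windowed-attention backbones place the
same norm where stage outputs feed heads.

**Cross-attention.** Both grids are flattened, layer-normalized, and
projected to a common dim d_c = 2D with 8 heads. The core is exactly
scaled dot-product attention with per-query softmax normalization;
queries from S3 against keys/values from S1 give F3, and symmetrically
F1. Outputs are projected back to each grid's own dimension and added
residually (the standard pre-norm cross-attention layer). An optional
`pool_fine_kv` flag average-pools the fine grid's keys/values 2× per axis
to bound memory at large inputs; it is off by default.

**Decoder** (the architecture description stops at the encoder, so this
is package plumbing): F3 is 1×1-projected, bilinearly upsampled ×4,
SE-fused with the projected F1 map, channel-gated by `σ(1×1(g))` where g
is the conv branch's pooled vector, then two upsample→3×3 conv→BN→ReLU
stages and a final 1×1 conv give one logit channel at full resolution.
Prediction threshold 0.5 on sigmoid probabilities.

**SE blocks.** GAP → FC(C/r) → ReLU → FC(C) → sigmoid → scale, ratio
r = 16 at reference scale (8 in the reduced config so r divides every
recalibrated channel count). The squeeze layer is initialized with zero
weights and bias 0.1: behind global pooling its input is nearly
sample-independent at initialization, so a random wide init can leave the
narrow bottleneck entirely ReLU-dead for a whole run; the neutral-active
start has pre-activations equal to the bias while weight gradients
(proportional to the pooled features) flow immediately.

**Ablation variants** are constructed, not simulated: `se_swin_only`
drops the conv branch and its fusions (the decoder gate then pools S3);
`se_conv_only` drops the attention branch and runs cross-attention on
1×1-projected conv reshapes; `skip_fusion` replaces every SE-fusion with
projected elementwise addition; `no_cross_attention` feeds S1/S3 straight
to the decoder. Parameter counts are strictly ordered
full > skip_fusion > no_cross_attention > se_conv_only > se_swin_only;
the absolute counts depend on (D, depths, channels), which the reference
description does not pin, so only the ordering is treated as meaningful.

## Loss and metrics

`L = α·BCE + (1−α)·softDice`, α = 0.5. BCE takes probabilities clamped
to [1e-7, 1−1e-7]; soft Dice uses smoothing 1e-6, is computed per image
and averaged over the batch. Hard metrics (Accuracy, Precision, mIoU =
mean of foreground and background IoU, DSC, all percent) come from
thresholded predictions at 0.5 and are micro-averaged: confusion counts
are summed over the dataset before the formulas are applied. 0/0 ratios
report 100 when the reference set is empty and the prediction agrees,
else 0. Metrics are computed full-frame; an FOV mask can be applied by
the caller before counting.

## Training protocol

Adam (β₁ = 0.9, β₂ = 0.999), weight decay 1e-5 added to the raw
gradient, lr 1e-4, batch 4, up to 200 epochs — these defaults mirror the
published protocol. The scheduler is reduce-on-plateau: lr ×0.1 after 10
consecutive epochs without the validation loss improving by more than
1e-6 (ties count as stagnation); under stagnation from epoch 1 the first
reduction lands at epoch 11. Early stopping fires after 20 stagnant
validation-Dice epochs; the checkpoint with the highest validation Dice
is kept, earliest epoch on ties. Training augmentation (flips p=0.5,
rotation ±10°, brightness/contrast ±0.2, and — each with p=0.3 — elastic
deformation (α=40, σ=6) and Gaussian noise) applies geometric transforms
identically to image and mask and re-binarizes the mask; evaluation
loaders have no augmentation stage at all. The ±0.2 and elastic
magnitudes are package choices; the source protocol gives only the
rotation range and the 0.3 probability. A `mixed_precision` flag is
accepted for config compatibility but the numpy backend has no
half-precision kernels, so it warns and runs in float32.

**Precise-BN.** Before each validation pass the BatchNorm running
statistics are re-estimated as the average batch statistics over the
training set under the current weights. With small batches and a
fast-moving optimizer the exponential running averages lag the weights
badly enough to decouple eval-mode from train-mode behaviour; the
re-estimation pass (a handful of forward passes at desk scale) closes
that gap deterministically.

**Desk-scale runs.** The learning-capability experiments use the reduced
configuration — D=24, channels (24, 48, 96), r=8, 128×128 input — with lr
5e-3 and batch 2 for up to 50 epochs. The higher rate and smaller batch
are the standard short-schedule adjustment: the runs take a few hundred
optimizer steps where the full protocol takes thousands, and the model is
~100× smaller than reference scale. The paper-scale defaults in
`TrainConfig` are unchanged.

**Splits.** `split_dataset` shuffles by seed and rounds train and val to
the nearest integer, remainder to test — the unique simple rule that
reproduces both 28 → (17, 6, 5) at 60/20/20 and 20 → (16, 4) at 80/20.
DRIVE's official 20/20 split is used verbatim, not re-split.

## Synthetic data

The generator emulates the statistical structure of fundus photographs:
a circular field of view, a smooth reddish-orange background with radial
illumination falloff and low-frequency shading, dark thin branching
curvilinear vessels, additive Gaussian noise (σ = 0.02), black outside
the FOV. Vessel masks are width-tapering random binary trees: walkers
start on the FOV boundary aimed inward, advance 1.4 px per step with
heading jitter N(0, 0.16 rad), taper ×0.987 per step, bifurcate with
probability 0.05 (children inherit a U(0.6, 0.8) width fraction), and
terminate below half-width 0.55 px or on leaving the FOV. Strokes are
stamped as anti-aliased discs and thresholded at 0.5, keeping masks
strictly binary and bitwise reproducible. The defaults (128 px side,
3 trees, root half-width 2 px) put the vessel fraction in 5–12% of
pixels for ≥ 18 of 20 seeds — the imbalance regime the Dice loss targets.

What it does *not* model: optic disc and fovea, pathology, camera noise
statistics, inter-grader annotation variability, or the resolution of
real fundus cameras (~1000 px). Passing the desk-scale learning tests
therefore shows the architecture, gradients, and protocol work end to
end on thin-structure segmentation under class imbalance; it does not
certify clinical-grade accuracy on real retinas, which requires training
at full scale on the public datasets.

## Numerical choices

float32 throughout the network; oracles and gradient checks run in
float64. Softmax is max-shifted; attention raises on non-finite logits
rather than propagating them; the cross-boundary mask value is −1e9.
Bilinear resampling uses half-pixel centres implemented as cached dense
per-axis interpolation matrices, so its adjoint is the exact transpose.
Convolution is im2col + BLAS matmul with a slice-accumulated col2im
backward. Patch merging concatenates 2×2 blocks in row-major order
(TL, TR, BL, BR) and maps 4E → 2E, honouring the stated D → 2D → 4D level
dims. All coordinates are 0-based row-major; token (row, col) ↔ image
(y, x). Checkpoints are single-file `.npz` archives holding a JSON
header plus parameter/buffer/optimizer arrays.

## Problem sizes used by the test suite

Unit oracles run on grids ≤ 8×8 and windows M ∈ {2, 3, 4}; structural
checks build the reference configuration (D=96, 512×512) for counting
only and a 64×64/D=8 model for forward/backward checks; the learning
experiments use the reduced 128×128/D=24 model on 8–20 synthetic pairs.
These sizes were chosen so the full suite and the acceptance script each
complete in a few minutes on a single CPU core while still exercising
every subsystem at realistic depth.

## Known limitations

The numpy engine is single-threaded BLAS-bound and has no GPU path, so
reference-scale training is out of reach here by design. The additive
(Er + Ec) position bias is strictly weaker than a joint 2D bias table.
The decoder is deliberately light and package-defined; alternative heads
(deep supervision, test-time augmentation) are out of scope. Whether S1
should be the fused level-1 input or the level-1 output is ambiguous in
the source description; the fused input was chosen and is documented
here.
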