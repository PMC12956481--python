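# Methods

## Problem and supervision model

The task is binary nucleus segmentation of RGB histology tiles when the
only human annotation is one pixel coordinate per nucleus. Dense
supervision is synthesised from the points in two complementary ways,
and the training design treats both as *noisy*:

* **Voronoi labels** `y_v`. The frame is partitioned into nearest-point
  cells (exact integer Euclidean distances, ties to the lowest point
  index). Pixels within `r_pt` of a point are positive, pixels whose
  `(2·ridge_width+1)`-square neighbourhood spans two or more cells are
  negative (minus the positives), the rest carry the unlabeled code 255.
  `r_pt = 2 px` and `ridge_width = 1 px` by default: dilated points give
  the attention loss a few certain-nucleus pixels per cell, and the
  one-pixel ridge band marks certain background between nuclei. Voronoi
  labels encode topology (one nucleus per cell) but say nothing about
  true boundaries.
* **Superpixel labels** `y_s`. SLIC with `n_segments = H·W/150` and
  compactness 10 oversegments the image; superpixels containing at
  least one point are foreground. These follow local colour boundaries
  but inherit SLIC's over/under-segmentation errors.

Two preprocessing options model annotation imperfection: point
perturbation by a fixed radius `r` (each point moves by the integer
displacement whose norm is closest to `r` in a uniformly random
direction, so the realised shift stays within half a pixel of `r`; a
`range` mode draws `r ~ U[3, 5]` instead), and Reinhard colour
normalisation (per-channel LAB mean/std matched to a reference image;
a constant-valued image is passed through with a warning).

## Networks

Three branches train jointly ("SAC-Net"):

* **SegNet** — residual encoder (stem + four stages; the last stage
  trades stride for dilation rate 2) and an additive decoder: a 1×1
  transform of the upper features, bilinear upsample when one pyramid
  level apart, element-wise addition with the encoder skip, then a
  1×1/3×3/1×1 convolution stack. The three decoder outputs pass through
  CBAM blocks (channel attention from a shared two-layer MLP over
  global max/avg pools, combined additively before the sigmoid; spatial
  attention from channel-wise max/mean maps through a 7×7 convolution),
  are projected to a common width, summed element-wise, reduced to one
  channel and bilinearly upsampled to input resolution; a sigmoid gives
  the foreground probability. Inputs are standardised uint8 RGB, padded
  internally to a multiple of 16 and cropped back.
* **AttNet** — the same decoder/aggregation design on a smaller encoder,
  with a 4-channel input (RGB + `y_s` as a 0/1 plane). It rejects label
  maps containing the unlabeled code.
* **ConsNet** — conv1 (full resolution) and conv2 (stride 2), each
  3×3/BatchNorm/ReLU at width 32 (scaled by the width multiplier); a
  side branch (average-pooled to the encoder's first-stage stride when
  that stride is 4) passes through conv3 to match encoder-1's channel
  count, giving `f_cons`, which is added element-wise into SegNet's
  first encoder stage; the main branch bilinearly upsamples conv2's
  features to full resolution, then conv4 and a linear 3×3 conv5
  produce the N-channel output `h` (N = 3 by default; the channel count
  is a free capacity knob of the constraint branch). conv5 is linear —
  `h` approximates the probability map through the L1 pull rather than
  through a squashing nonlinearity.

Deformable convolution (a plain convolution predicts per-tap (dy, dx)
offsets; the main kernel samples the input bilinearly at the displaced
positions, zero outside the frame) can replace every 3×3 encoder
convolution via `use_deformable`. Offset predictors initialise to zero,
so the layer starts exactly equal to its rigid counterpart — this
equivalence is asserted in the tests, and the option is off in the
desk-scale profile because it is the most expensive operation on CPU.

### Encoder families

| family | blocks/stage | widths | stem stride | feature strides |
|---|---|---|---|---|
| resnet50 | 3/4/6/3 bottleneck | 256/512/1024/2048 | 2 | 4/8/16/16 (dilated last) |
| resnet18 | 2/2/2/2 basic | 64/128/256/512 | 2 | 4/8/16/16 (dilated last) |
| tiny | 1/1/1/1 basic | 64/128/128/128 | 1 | 2/4/8/8 (dilated last) |

All widths scale by `width_multiplier` (floor 4). The tiny profile—the
one the test suite and synthetic runs use, at multiplier 0.25—halves
every stride. The reason is geometric: on ~1000 px histology tiles a
nucleus spans 30–50 px, so decoding from stride-4 features loses only a
small fraction of each nucleus; on the 96 px synthetic tiles nuclei are
~10 px, and stride-4 decoding would blur a boundary band comparable to
the nucleus radius. Halving the strides keeps the feature-to-nucleus
size ratio roughly what the full-width encoders see at native scale.
ConsNet's side branch adapts its stride to the encoder's first stage.

## Losses and gradient flow

With `(α, β, γ, δ) = (0.4, 0.8, 1, 0.4)`:

* `L_seg = BCE(f(I) ⊙ f_att, y_s)`, probabilities clamped to
  `[1e−7, 1−1e−7]`.
* `L_att = Σ_{p∈y_v⁺}|1−f_att(p)|/|y_v⁺| + α·Σ_{p∈y_v⁻}|1−f_att(p)|/|y_v⁻|`.
  Both labeled classes pull the map toward 1: `f_att` marks *confident*
  regions (nucleus core or certain background alike) and leaves the
  noisy boundary band low. The implementation follows this form as the
  default; `att_neg_target = 0` selects the alternative reading in
  which negatives pull toward 0, for ablation.
* `L_cons = (1/N) Σ_n mean |f(I) − h(I)_n|`. L1 rather than L2 so that
  boundary outliers in the pseudo-labels produce bounded gradients.
* `L_total = β·L_seg + γ·L_att + δ·L_cons`.

By default `f_att` is detached inside `L_seg` and `f(I)` inside
`L_cons`: AttNet learns only from the Voronoi loss and ConsNet's output
branch only from the constraint loss. Without the first detachment the
system has a degenerate optimum (`f_att → 0` zeroes the masked BCE on
background); `detach = false` restores fully joint gradients for
ablation. `L_seg` does flow into ConsNet through the `f_cons` merge —
the side branch is part of SegNet's forward path.

## Training recipe

Adam (lr 0.001, weight decay 0.0005 folded into the gradient), batch
size 1 with gradient accumulation for larger settings, 60 epochs in
the full-scale profile. 20% of images (at least one) are held out per seed as a
validation split; the validation `L_total` is evaluated each epoch in
eval mode and the learning rate halves when it fails to improve for 4
consecutive epochs. The best-validation parameters are checkpointed.
Augmentation per training sample: random affine (rotation ±30°, scale
0.8–1.2, shear ±10°), horizontal/vertical flips, Gaussian blur
(σ ∈ [0, 1]) and hue/saturation jitter; geometric transforms are applied
identically to the image, both label maps (nearest-neighbour, unlabeled
fill for the Voronoi map) and the points, photometric ones to the image
only. A draw that leaves the Voronoi label without positives or
negatives falls back to the unaugmented sample for that step. All
randomness (init, splits, ordering, augmentation) derives
deterministically from the config seed, so fixed-seed runs are
bit-reproducible on CPU.

## Confident learning

For each image (default scope) the stage-1 model's eval-mode
probabilities `p̂(1) = f(I)`, `p̂(0) = 1 − f(I)` and the given labels
define:

1. thresholds `t_j` = mean `p̂(j)` over pixels labeled `j`;
2. counting matrix `C[i][j]` = number of pixels labeled `i` whose argmax
   class is `j` with `p̂(j) > t_j` (relaxed to `≥` when `t_j = 1`, so
   perfectly one-hot predictions are not discarded);
3. joint distribution `Q`: rows of `C` rescaled to the labeled-class
   frequencies, then normalised to total 1;
4. correction: per off-diagonal cell, the `round(n·Q[i][j])`
   (half away from zero) pixels with the largest margin
   `p̂(j) − p̂(i)` are flipped — drawn from that cell of the counting
   matrix, i.e. from the confidently mispredicted pixels, so the flip
   count is also capped by `C[i][j]`; if the budget exceeds the
   candidates, all candidates flip and a warning is logged.

`scope = "pooled"` estimates one noise model over all pixels instead;
`per_image` is the default because the refinement is defined per
training image and per-image thresholds track per-image stain/contrast.
One refinement round is the default — repeated rounds drag the labels
toward the model's own biases, degrading them (the same direction
reported for the original method). Stage 2 then retrains the whole
three-branch network from scratch on `y_re`, which also replaces `y_s`
in AttNet's fourth input channel.

## Synthetic data

`generate_scene` renders rotated ellipses (semi-axes 4–12 px at a 96 px
frame, scaling linearly with frame size) with per-instance colour
jitter (σ = 15 around nucleus RGB (110, 70, 140)) on a background of
RGB (230, 200, 220), plus per-pixel Gaussian noise (σ = 8) — contrasts
chosen so SLIC boundaries are informative but imperfect. Overlap up to
pairwise IoU 0.30 is allowed by default (touching nuclei are the hard
case); disjoint placement can be requested and raises after a bounded
number of attempts if impossible. Centroids are recomputed from the
rendered (possibly frame-clipped) masks, snapped into the mask, and
deduplicated across instances. Per-image seeds derive from the master
seed through `SeedSequence`.

What the generator does *not* emulate: real stain chemistry and
scanner variation, chromatin texture inside nuclei, non-elliptical and
clustered morphologies, mitotic figures, background structures (stroma,
cytoplasm, glands). Passing tests therefore demonstrate that the
pipeline's mechanics are correct and that its improvement directions
hold under controlled noise — not that the accuracy figures transfer to
MoNuSeg/TNBC-class data, which would need the full-scale profile on
real images.

## Problem sizes and numerical choices

The bundled end-to-end profile (`desk_scale_config`) is 16 synthetic
96×96 images, tiny networks, 5 epochs per stage — a full two-stage run
in well under two minutes on one CPU, sized so the whole suite and the
acceptance script rerun quickly anywhere. Larger runs only change the
config.

Numerics: training arithmetic is float32 (float64 is preserved when
supplied, and the scalar loss examples in the tests are checked in
float64); BCE clamp 1e−7; batch-norm uses biased variance for both
normalisation and running statistics (momentum 0.1) and eval mode uses
the running values; bilinear resampling uses half-pixel centres with
clamped edges; evaluation thresholds `f(I)` at 0.5 (no binarisation
rule is prescribed for the probability maps); IoU/Dice define
both-empty masks as 1; Voronoi ties resolve to the lowest point index;
margin ties in confident learning resolve to the lowest pixel index via
a stable sort.

## Known limitations

* Stage-2 retraining does not always improve the *model* metrics at
  desk scale even when it improves the labels — five epochs from
  scratch on 16 images is near the noise floor of the comparison; the
  asserted, reproducible effect is the label-quality direction.
* Only binary (nucleus/background) segmentation; no instance metrics
  (AJI) and no multi-class confident learning.
* The NumPy engine is single-threaded and eager; the full-scale
  ResNet-50 profile is functional but meant for small batches of tiles,
  not whole-slide throughput.
* Whole-slide (pyramidal) formats are out of scope; images are PNG/TIFF
  tiles.
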