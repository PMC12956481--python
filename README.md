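# sacseg — weakly supervised nucleus segmentation from point annotations

Pixel-accurate nucleus segmentation in histology images normally needs
dense masks that only pathologists can draw. `sacseg` trains a
segmentation network from **one point per nucleus** instead, for
researchers who have centroid click-annotations (or can make them
cheaply) but no pixel-level ground truth.

The package implements a two-stage weakly supervised framework:

1. **Pseudo-labels from points.** Each image's points induce two
   complementary label maps: a *Voronoi label* `y_v` (nearest-point
   partition; small discs around points are positive, inter-cell ridges
   negative, everything else unlabeled) and a *superpixel label* `y_s`
   (SLIC oversegmentation; superpixels containing a point are
   foreground).
2. **Stage 1 — SAC-Net.** Three networks train jointly:
   - **SegNet** `f(I)`: a residual encoder–decoder with CBAM-based
     feature aggregation producing the per-pixel foreground probability;
   - **AttNet** `f_att = g(c(I, y_s))`: the same design on a smaller
     encoder, fed the image concatenated with `y_s`, supervised by the
     Voronoi label, producing a confidence mask that excludes noisy
     boundary regions from the segmentation loss;
   - **ConsNet**: a shallow constraint network whose side branch
     `f_cons` is added into SegNet's first encoder stage and whose
     N-channel output `h(I)` is pulled toward `f(I)` by an L1 loss,
     preserving low-level texture.

   The objective is
   `L_total = β·L_seg + γ·L_att + δ·L_cons` with
   `L_seg = BCE(f(I) ⊙ f_att, y_s)`,
   `L_att = Σ_{y_v⁺}|1−f_att|/|y_v⁺| + α·Σ_{y_v⁻}|1−f_att|/|y_v⁻|`,
   `L_cons = (1/N) Σ_n |f(I) − h(I)_n|`, and
   `(α, β, γ, δ) = (0.4, 0.8, 1, 0.4)`.
3. **Stage 2 — confident learning.** The trained model predicts the
   training images; per-class confidence thresholds `t_j`, a counting
   matrix `C[i][j]` of pixels labeled `i` but confidently predicted `j`,
   and its calibrated joint distribution `Q` estimate the label noise.
   The `round(n·Q[i][j])` highest-margin pixels in each off-diagonal
   cell are flipped, and the whole network retrains on the refined
   label `y_re`.

Everything runs on plain NumPy: the package ships a compact
reverse-mode autodiff and CNN toolkit (`sacseg.nn` — convolution,
batch-norm, CBAM pooling, bilinear resampling, deformable convolution,
Adam), so desk-scale training needs one CPU and no GPU stack.

A bundled synthetic-histology generator (`sacseg.synthetic_data`)
renders H&E-like scenes — textured elliptical nuclei on a lighter
background with exact instance masks and centroids — so the entire
pipeline is testable end-to-end without downloading any dataset. Real
images with point CSVs in the same layout work identically.

## Worked example

```bash
sacseg run-full --out runs/demo --seed 1
```

generates 16 synthetic 96×96 images, builds pseudo-labels, trains both
stages (tiny network profile, 5 epochs each), refines the superpixel
labels with confident learning, and evaluates against the known ground
truth. `runs/demo/result.json` from this exact command:

```json
{
  "stage1": {"metrics": {"iou": 0.785, "dice": 0.880}},
  "stage2": {"metrics": {"iou": 0.750, "dice": 0.856}},
  "label_quality_fraction_improved": 0.9375
}
```

Reading the numbers: with only centroid points as supervision, the
stage-1 model reaches a mean pixel IoU of 0.785 against the hidden
masks; confident learning then raises the superpixel labels' pixel
accuracy on 15 of 16 images (mean 0.901 → 0.932 in
`label_quality.json`), the direction the method is built to deliver.
A fully supervised U-Net reference on the same images
(`baseline.enabled: true` in the config) scores a mean Dice of 0.900 —
the weakly supervised result approaches but does not beat dense
supervision.

Every step is also exposed separately (`sacseg generate-synthetic`,
`make-pseudolabels`, `train-stage1`, `refine-labels`, `train-stage2`,
`evaluate`), all driven by one YAML config; see
`sacseg.pipeline.default_config()` for the schema and the full-scale
defaults (60 epochs, ResNet-50-class encoder).

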