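# Methods

`odcseg` implements a glaucoma-specialized optic-disc/optic-cup (OD/OC)
segmentation framework for colour fundus photographs: a pixel-supervised
U-Net whose predictions are pushed toward the glaucoma class by two
class-level signals — a Gram-matrix style-contrastive loss and two-space
domain-adversarial learning — together with the glaucoma-oriented
evaluation suite (per-region Dice, CDR mean squared error, G-score) and
a synthetic fundus-ROI generator that makes the whole pipeline testable
end to end without clinical data.

## Model

**Segmenter.** A customized U-Net over 3×H×W RGB inputs (H, W divisible
by 16). Encoder: four Double-Conv (3×3 conv → batch norm → ReLU, twice)
stages of widths *b*, 2*b*, 4*b*, 8*b* with 2×2 max-pooling, plus a
Double-Conv bottom at width 8*b*. Decoder: bilinear upsampling,
concatenated skip connections, Double-Convs of widths 4*b*, 2*b*, *b*,
*b*/2, and a final 3×3 convolution to three classes followed by a
channel softmax. The three classes — background, neuroretinal rim, cup —
are mutually exclusive; the disc is reconstructed as rim ∪ cup. Two
feature spaces are exposed: the first decoder stage ("Up1") output
(width 4*b* at 1/8 resolution, the *encoding space*) and the softmax map
(the *output space*). At the reference width *b* = 64 with 256×256
inputs these are 256×32×32 and 3×256×256. Desk-scale tests use *b* = 8
and 64×64 inputs (32×8×8 / 3×64×64 by the same arithmetic).

**Domain discriminators.** One small fully-convolutional patch
classifier per space: three 4×4 stride-2 convolutions and one 3×3
convolution with LeakyReLU(0.2), then a 3×3 convolution to one logit
channel — an exact 8× downscale, e.g. 1×32×32 patch logits for a
3×256×256 input. Channel progression is 3→6→12→24→1 for the output
space and scales proportionally for the encoding space. The encoding
discriminator consumes the Up1 feature at its native 1/8 resolution; an
`upsample_encoding` switch first bilinearly upsamples it to the image
grid for users who want the literal full-resolution variant (it adds no
information and is memory-hostile, so it is off by default).

## Losses

* **Soft Dice** (pixel supervision): per channel,
  `1 − 2Σ(p·y)/(Σp² + Σy² + ε)` with sums over all pixels, averaged over
  the three channels; ε = 1e−7. Zero for a perfect one-hot match, 1 for
  a total miss.
* **Gram matrix / style gap** (style contrast): `Gram(F) = RᵀR` with
  `R` the HW×C reshape of a C-channel map. The style gap between two
  predictions is `Σ_{r,c}(Gram_a − Gram_b)²/(C²·HW)`, i.e. Gram
  matrices are compared after a single division by the pixel count.
  This normalization is deliberate: raw softmax-map Grams grow with the
  squared pixel count, and the squared difference of one-hot-scale Grams
  is O(10⁵–10⁶), which would make the shipped style weight of 0.05 crush
  the Dice term (we observed exactly this collapse). Dividing once by HW
  puts the gap on a scale where 0.05 is a meaningful secondary pull at
  both desk (64²) and reference (256²) sizes. `gram_matrix` itself
  returns the unnormalized matrix.
* **Discriminator BCE** (domain supervision): patch-wise binary
  cross-entropy with glaucoma = 1, normal = 0, mean over patch
  positions; sigmoids are clipped to [ε, 1−ε].
* **Adversarial domain gap** (generator side): for normal-sample
  predictions, `−log σ(D(·))` per patch in each space — the cost of the
  discriminator *not* being fooled into the glaucoma label — combined as
  `w_e·L_enc + w_o·L_out` with `w_e = 0.2`, `w_o = 0.8` (must sum to 1).
* **Total objective**:
  `w_seg·L_seg + w_style·L_style + w_domain·(w_e·L_enc + w_o·L_out)`.

All patch/pixel reductions are means for scale stability;
`reduction="sum"` reproduces raw sums where exposed.

## Training procedure

Each iteration processes a two-image batch (one pixel-annotated source
sample, one unannotated target glaucoma sample) and alternates:

1. **Segmenter step** — discriminators frozen (their parameters are
   bit-identical before and after; this is contract-tested), one Adam
   update of the segmenter on the weighted objective. Unannotated images
   contribute only through the style/domain terms, never through Dice.
2. **Discriminator step** — segmenter frozen, features regenerated from
   the just-updated segmenter and detached, one Adam update of each
   discriminator on its patch BCE with true domain labels. Requires both
   domains in the batch.

Optimisers: Adam, betas (0.9, 0.99); learning rate 1e−4 for the
segmenter and 1e−2 for the discriminators, both decayed per epoch by
StepLR with gamma 0.95. Default input 256×256×3 (64×64 at desk scale),
batch size 2.

**Two-phase schedule.** A warm-up phase runs weights
(w_seg, w_style, w_domain) = (1.0, 0.05, 0.0) — supervised learning plus
the style pull, no adversary. A refinement phase then activates the
adversarial term (w_domain = 1.0) and runs the dual-step alternation.
Two schedule choices were genuinely open and we fixed them empirically:

* *Phase boundary* (`phase1_fraction`, default 0.8). The procedure
  premises refinement on an already-optimized supervised model. At the
  30-epoch desk scale, supervised training has not converged by the
  midpoint (the Dice loss is still falling at epoch 30), and every epoch
  of premature adversarial refinement measurably degrades validation
  M-Dice. The default therefore spends 80% of the budget on warm-up;
  any other split is one config key away.
* *Refinement weights* (`keep_seg_in_phase2`, default on). The dual-step
  update rule applies all three weighted losses in every segmenter step,
  so the default keeps (1.0, 0.05, 1.0) during refinement. With the flag
  off the refinement phase runs the bare adversarial setting (0, 0, 1.0);
  in our experiments that unanchored variant drifts monotonically away
  from correct segmentation (validation M-Dice 0.32–0.38 vs 0.50 for a
  purely supervised run under identical conditions).

**Clinical scenarios.** Scenario 1: annotated normals (source) +
unannotated glaucomas (target). Scenario 2: an annotated glaucoma subset
(source) + unannotated glaucomas (target) — adversarial learning is
undefined without both domains, so the run keeps warm-up weights
throughout, performs zero discriminator updates (contract-tested), and
pairs annotated-glaucoma with unannotated-glaucoma predictions in the
style term. Scenario 3: both classes annotated; style/domain pairs are
drawn across domains inside the source pool.

Style pairing in general: all normal×glaucoma prediction pairs in the
batch when both domains are present, otherwise annotated×unannotated
pairs within the class.

**Diagnostics.** Every epoch records the mean loss components plus the
*style gap to glaucoma ground truth*: the mean style gap between each
glaucoma-validation prediction and its one-hot ground truth — the curve
that should fall faster when the class-level modules are active — and
the validation M-Dice.

## Evaluation suite

* **Dice** per region (disc, cup, rim) from argmax-decoded predictions;
  `2TP/(2TP+FP+FN)`; both-empty pairs score 1.0 (a correct negative is
  not penalized). **M-Dice** is the mean over the three regions.
* **CDR**: cup-to-disc ratio of axis-aligned bounding-box extents of the
  largest connected component of each structure, in the vertical and
  horizontal directions; raw extents rather than fitted ellipses, which
  is robust to stray pixels. **CDR_MSE** = mean over samples of
  (ΔCDR_H)² + (ΔCDR_V)².
* **G-score**: `(mean IoU of disc and cup)·100/2 −
  |vCDR_pred − vCDR_gt|/vCDR_gt·100`, averaged over samples; 50 is a
  perfect score, and the score is not clamped below. The overlap region
  (mean disc/cup IoU) and CDR direction (vertical) follow the
  glaucoma-challenge lineage convention and are config-exposed.

An empty predicted disc contributes CDR (0, 0).

## Synthetic data

The generator emulates the two class differences the framework exploits,
at ROI scale (the disc region already cropped):

* **Morphology** — elliptical disc (radius 0.28–0.36 of the half image
  size, mild eccentricity 0.85–1.0, rotation ±15°) with a nested
  elliptical cup; per-axis cup/disc ratios drawn from the class CDR
  range, normal (0.3, 0.5) vs glaucoma (0.6, 0.85). The ranges are
  disjoint, so the measured vertical CDR separates the classes
  perfectly (property-tested); the cup centre is jittered within 15% of
  the free margin so cups are not trivially concentric. Geometries whose
  rasterized cup escapes the disc or whose disc touches the canvas are
  rejected and redrawn.
* **Style** — reddish background with a radial vignette, brighter disc,
  brightest cup, dark quadratic-Bezier vessel strokes radiating from the
  disc, Gaussian texture noise, slight blur; the glaucoma pool carries a
  mild red-shifted colour gain (1.12, 0.92, 0.85), one extra vessel and
  slightly stronger noise/blur. The magnitude of this style shift is a
  free design choice (no clinical reference quantifies it); it is set so
  the class channel means separate by more than twice the within-class
  spread — visible to the discriminators but far from trivial.

Masks are the exact rasterized ellipses (noise-free ground truth). Every
split draws from its own named random stream derived from the master
seed, so a (seed, config) pair determines every pixel and enlarging one
split never perturbs another. What the generator does **not** emulate:
photorealistic texture, pathology other than cup enlargement,
peripapillary atrophy, illumination artefacts, annotation noise, or the
subtlety of real normal-vs-glaucoma style differences — passing tests
show the machinery is correct and directionally effective on separable
synthetic classes, not that clinical-grade accuracy is reached.

## Desk-scale benchmark

The shipped efficacy study (`odcseg.benchmark.run_benchmark`, also run
by `scripts/acceptance.py` and the acceptance tests) trains, for each of
five seeds, the full style+domain model and a purely pixel-supervised
baseline on the same Scenario-1 dataset: 64×64 images, base width 8,
20 annotated normals, 12 unannotated glaucomas, 12 glaucoma-validation
samples, 30 epochs. These sizes keep a full five-seed comparison within
minutes on one CPU core while preserving the architecture arithmetic
(all shapes scale by 1/8 from the reference configuration). Reported
quantities: per-seed and mean glaucoma-validation M-Dice, CDR_MSE,
G-score, and the final style gap to glaucoma ground truth, for both
models. At this scale the supervised model is still far from
convergence after 30 epochs (M-Dice ≈ 0.2–0.5 depending on seed), so
the comparison is directional — the interesting quantities are the
full-vs-baseline differences, not absolute accuracy.

## Numerical choices

* All tensors float32; the autodiff core (`odcseg.nn`) is numpy-only and
  fully deterministic, so identical (config, seed, data) reproduces
  results bit-for-bit.
* Convolution backward accumulates input gradients per kernel offset;
  max-pool routes gradients to the argmax (first index on ties);
  bilinear resize uses precomputed interpolation matrices
  (align-corners-false convention), making its transpose the exact
  backward.
* He-normal initialisation driven by per-model seeded generators; batch
  norm momentum 0.1, eps 1e−5; Adam eps 1e−8.
* ε = 1e−7 floors inside all logs and Dice denominators.
* CLAHE runs on the CIELAB luminance channel (chrominance preserved)
  with an OpenCV-convention clip limit (default 2.0 on an 8×8 tile
  grid) mapped to skimage's normalized clip as `clip_limit/256`; a
  per-channel RGB switch is exposed. ROI crops use 0-based half-open
  boxes; images resample bilinearly, masks by nearest neighbour.

## Known limitations

* The adversarial min–max at desk scale is sensitive to the phase
  budget: long unanchored refinement degrades segmentation (see the
  schedule discussion above). The literal printed schedule remains
  reachable via config for study.
* Validation uses batch-norm running statistics; very short runs
  evaluate with partially warmed statistics.
* Seed-to-seed variance at 30 desk-scale epochs is large; single-seed
  comparisons are not meaningful, which is why every shipped comparison
  aggregates five seeds.
* The G-score can be dominated by the relative-CDR penalty for weak
  models (large negative scores are expected early in training).
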