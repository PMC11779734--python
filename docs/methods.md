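# Methods

This note documents the models and algorithms implemented in `dfma`, the
parameter choices that matter, the synthetic data the tests rely on, and
the known limitations.

## Segmentation network

The network is an encoder–decoder in the DeepLabv3+ mould, specialised for
four classes (background, shoot, root, seed).

**Backbone.**  Four stages of residual FasterNet-style blocks,
`y = x + PWConv₂(ReLU(BN(PWConv₁(PConv(x)))))`, preceded by a 4×4 stride-4
embedding convolution and separated by 2×2 stride-2 merge convolutions.
The partial convolution (PConv) convolves only the first `c_p = ¼·c`
channels (the FasterNet convention; the fraction is configurable) and
passes the rest through unchanged, cutting the spatial-mixing cost by
`(c_p/c)² = 1/16`.  Default stage depths are (1, 2, 8, 2) with widths
(40, 80, 160, 320), a small FasterNet-T-like variant; both are
configurable because segmentation quality is insensitive to the exact
variant at the scales we test.  The pointwise expansion factor is 2.
Normalisation is batch normalisation, activation ReLU.  The stage-1 output
(stride 4) is kept as the decoder's skip feature; the stage-4 output
(stride 32) feeds the context modules.

**EMA attention.**  Channels are folded into g = 8 groups processed
independently with shared weights.  Per group: height- and width-wise
global average pooling feed one shared 1×1 convolution whose split outputs
gate the features directionally (sigmoid), followed by group
normalisation; a parallel 3×3 convolution gives a local route; each
route's softmax-normalised pooled descriptor is matrix-multiplied with the
other route's flattened spatial map, and the sigmoid of the summed result
re-weights the group (per-pixel weights in (0, 1)).  The 3×3 convolution
uses edge (replicate) padding: with zero padding a spatially constant
input would produce border-dependent attention, breaking the symmetry
property the tests verify.  EMA is applied to the stride-32 map before the
pyramid by default; a second post-pyramid application is config-gated off.

**PSPA pyramid.**  Four parallel branches over the stride-32 input:
(A) a 3×3 partial convolution followed by a 1×1 projection to 256
channels; (B) dilated 3×3 convolutions at rates 2 and 3, 128 kernels each,
concatenated; (C) the same at rates 5 and 7; (D) global average pooling,
1×1 convolution, broadcast back to the grid.  All branch outputs are
concatenated and fused by a 1×1 convolution to 256 channels; every
convolution carries BN + ReLU.  A serial variant (pair (5, 7) consuming
pair (2, 3)'s output) exists behind `serial=True`; the parallel layout is
the default since it is the conventional pyramid form.  Rates within a
pair are validated to be coprime — stacked dilated convolutions sharing a
common divisor produce the gridding effect, quantified by
`grid_coverage`: brute-force propagation of reachable offsets shows a
stack of three rate-2 layers touches only (7/13)² ≈ 29% of its 13×13
receptive field, while mixed rates (2, 3) reach 67%.  An analytic MAC
counter confirms the halved branches keep the pyramid cheaper than a
classic three-branch 256-wide pyramid at the same input.

**CARAFE upsampling.**  Kernel prediction: 1×1 compression to C_m,
a k_encoder×k_encoder encoder producing σ²·k_up² channels, pixel-shuffle
to a k_up×k_up kernel per output position, softmax over the k_up² logits
(the normaliser guarantees convex-combination weights; it is the canonical
choice).  Reassembly: output position l′ maps to source l = ⌊l′/σ⌋ and dot-
products its kernel with the zero-padded k_up×k_up neighbourhood; all
channels share the position's kernel.  Defaults k_up = 5, k_encoder = 3,
C_m = 64.  One σ = 8 module lifts the pyramid output from stride 32 to
stride 4; after decoding, the classifier runs at stride 4 and a σ = 4
CARAFE (nearest-neighbour switchable) restores the 4-channel logit map to
input resolution — upsampling after classification makes the final stage
cheap without changing the output contract.

**Decoder.**  The stride-4 skip feature is projected to 48 channels (the
DeepLabv3+ convention), concatenated with the upsampled context, refined
by one FasterNet block plus a 3×3 convolution to 256 channels
(`decoder_blocks` configurable), then classified.

**Numerical substrate.**  All layers run on `dfma.nn`, a small NumPy
reverse-mode autodiff engine (im2col convolutions, tape-based backward,
float32 working precision).  Every primitive's vector–Jacobian product is
verified against central finite differences in the test suite.  Batch
normalisation uses batch statistics in training and running statistics at
inference, so evaluation is bit-deterministic.

## Training

Loss is cross-entropy plus soft Dice with smoothing ε = 1, Dice averaged
over the classes present in the batch (empty classes would contribute a
degenerate ε/ε term).  The default optimiser is SGD with momentum 0.937
and weight decay 5·10⁻⁴ under a cosine schedule from 0.005 to 0.0001 over
at most 500 epochs, batch size 8; Adam is available by configuration.
Early stopping halts training when the validation loss has not improved
for 20 consecutive epochs, and the best-validation weights are restored.
Online augmentation (train-only) provides 90°-multiple rotations,
horizontal flips with probability 0.5, random scaling in [0.25, 2] with
aspect jitter, random crop/shift with gray padding (image value 128, mask
label background), and HSV jitter; geometry is applied identically to
image and mask (nearest-neighbour), photometry to the image only.

**CPU-scale experiment.**  The end-to-end check trains a width-reduced
model (widths ×0.25, depths (1, 1, 2, 1), k_up = 3) on 64 synthetic
128×128 close-up scenes with Adam at 2·10⁻³ for at most 30 epochs, batch
8.  Adam is used here because SGD at 0.005 needs far more epochs at this
data scale; 2·10⁻³ is a standard Adam rate.  Under seed 1 this reaches
validation mIoU ≈ 0.85, crossing 0.8 around epoch 12 (~2 minutes on one
CPU core).

## Length measurement

**Skeletonization.**  Hilditch thinning: a pass deletes every foreground
pixel whose 8-neighbour count lies in [2, 6], whose crossing number is 1,
and whose north/east co-candidate conditions hold; passes repeat to a
fixed point (cap 500).  On dense or looped patterns the parallel passes
can terminate with fully occupied 2×2 squares — a known limitation of the
deletion conditions — so a sequential cleanup removes block pixels whose
punctured 3×3 neighbourhood has exactly one 8-connected component (the
exact local-simplicity test; the crossing number alone misses diagonal
links between ring arcs).  The resulting skeleton is unit-width, contained
in the source mask, and never gains components.

**Length estimation.**  The default estimator extracts each component's
longest geodesic path (double-sweep Dijkstra over the 8-connected pixel
graph with 1/√2 edge weights) and measures a polyline through every 5th
path pixel, averaged over both traversal directions so the stride
remainder cannot bias the result.  Chords through collinear pixels are
exact — a 101-pixel straight line measures exactly 100, a perfect diagonal
exactly 10√2 — and the subsampling suppresses raster-staircase inflation:
raw chain-code edge counting overestimates oblique straight lines by up to
8% and staircased thinning output by up to 41%, which would dominate the
error budget.  On a rasterized quarter-circle of radius 100 the estimator
is within 0.3% of 50π.  The raw edge count (1 per axial, √2 per diagonal
edge, corner-shortcut diagonals excluded) remains available as
`method="edge_sum"`; it is the appropriate choice when side branches
(e.g. lateral roots) should add to the total.  The geodesic path measures
the main axis only; branched inputs therefore report their longest axis by
default.

**Coin detection and calibration.**  Canny edges (σ = 2) vote along their
smoothed-gradient direction at every radius in [r_min, r_max] (default
10–200 px), on both sides; the 3×3-smoothed accumulator peak is the
centre, the radius is the mode of centre-to-edge distances refined by
averaging within ±1 px, and an accumulator threshold (default 30 votes)
rejects scenes without a circular object.  Calibration divides the known
coin diameter (25 mm) by the detected pixel diameter.  On synthetic
scenes, centre and radius are recovered to well under 1 px, and a skeleton
exactly one coin diameter long measures 25 mm to within raster tolerance.

**Instances.**  A seedling instance is an 8-connected component of the
non-background mask; shoot and root lengths are measured on that
component's class regions separately.  Touching seedlings merge into one
instance (and are measured as one); components with neither shoot nor root
are skipped and logged.

## Synthetic scenes

The generator emulates a germination board photographed from above: a dark
noisy field, per seedling an elliptical seed with a shoot and a root
stroke leaving opposite ends of its major axis, and one bright filled disc
as the reference coin (label: background).  Strokes follow quadratic
Bézier centerlines — a parabola segment cannot self-intersect — with
turning angles bounded at 0.6 rad per control leg so the thick stroke does
not overlap itself; candidates whose shoot and root footprints overlap are
rejected, since overlap destroys the one-class-one-centerline
correspondence that defines ground truth.  Strokes are rendered by
stamping discs of the stroke width along a 2000-segment polyline (so the
skeleton tracks the generating curve), starting 1 px inside the seed rim
to keep the instance 8-connected.  Ground truth records each curve's arc
length by fine polyline integration, the coin geometry, and the implied
mm-per-pixel scale.  Default scene: 512×512, five seedlings, seed
semi-axes 7–12 px, arc lengths 60–180 px, shoot width 5–9 px, root width
3–6 px, coin radius 40–60 px, Gaussian noise σ = 6.  `SceneSpec.close_up`
is the 128×128 variant with the same organ pixel widths and a reduced
field of view (3 seedlings, arcs 22–55 px, coin 10–14 px) used for
CPU-scale training.  Layout is rejection-sampled with bounded whole-scene
restarts drawn from the same seeded stream, so every scene is
deterministic in its seed.

What the generator does **not** model: perspective and lens distortion,
uneven illumination and shadows, specular reflection on the coin, root
hairs and laterals, touching or crossing seedlings, and natural colour
variation beyond per-pixel noise.  Passing tests therefore demonstrate
that the architecture can learn and the measurement chain is unbiased
under controlled geometry — not field-ready accuracy on photographs.

## Metrics

All metrics reduce a (k+1)×(k+1) pixel confusion matrix (rows = truth,
columns = prediction): per-class IoU = TP/(TP+FP+FN) with mIoU averaging
over classes present in truth or prediction (empty classes are excluded
and logged; an all-empty matrix is an error); precision TP/(TP+FP), recall
TP/(TP+FN), accuracy (TP+TN)/total, with undefined ratios flagged as NaN
rather than thrown.

## Known limitations

- Training at full 512×512 scale is possible but slow on the NumPy engine
  (seconds per image); the architecture is validated at full size in a
  single forward pass, and training experiments run width-reduced.
- Hilditch thinning is slightly anisotropic; thinning a 90°-rotated ribbon
  changes the measured length at the few-tenths-of-a-percent level (the
  length function itself is exactly rotation-invariant on a fixed
  skeleton, up to tie-breaking among equal-length geodesic paths).
- The geodesic length estimator under-reports branched structures by
  design; use `edge_sum` when laterals must count.
- Coin detection assumes exactly one circular object in the admissible
  radius range; two coins would contest the accumulator peak.
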