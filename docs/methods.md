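# Methods

## Detection model

Cell detection is posed as dense heatmap regression: a fully
convolutional network maps three consecutive focal planes of a
brightfield z-stack (stacked as channels) to a same-resolution map of
per-pixel cell confidence, and cells are read off as local maxima of
that map. The three-plane input carries the through-focus signature
that separates cells from focus-invariant artifacts such as lens
impurities: a cell's contrast is near zero in the focused plane and
grows — with opposite signs — above and below it. The default input
triplet is the focused plane and the two planes above it.

The network is a *reduced* U-Net: a symmetric encoder–decoder with one
level pair fewer than the canonical four-level architecture. The
intermediate activations of the full U-Net already localize the cells,
so removing a level halves memory and compute without hurting accuracy.
Concretely: `depth` (default 3) levels of two same-padded 3×3
convolutions + ReLU followed by 2×2 max-pooling, channels doubling from
`base_filters` (default 16; 8 at desk scale); a two-convolution
bottleneck; a mirrored decoder with 2× nearest-neighbour upsampling and
channel-concatenating skips; a 1×1 convolution + sigmoid head. Same
padding keeps the heatmap at input resolution, at the cost of mild
border artifacts. Input sides must divide by 2^depth; being fully
convolutional, the network accepts any such size without rebuilding,
which the training schedule exploits by switching patch sizes.

The network, its backward pass and the optimizer are written directly in
numpy (im2col convolutions over one BLAS matmul per layer). Weights use
He initialization; the head starts at zero, so an untrained detector
outputs exactly 0.5 everywhere. The analytic gradients are validated
against central-difference numerical gradients (in float64, with a small
step, since larger steps cross ReLU kinks) in the test suite.

## Training targets and class balance

Point annotations are rasterized into binary masks: a disk of radius
`max_radius` (default 8 px) per cell, with pixel (y,x) in a cell's disk
iff (y−r₀)² + (x−c₀)² ≤ r². When two cells' full disks would touch
(share a pixel or have 8-adjacent pixels), both radii shrink to
⌊(d−1)/2⌋ for centre distance d, then decrement further until an exact
lattice adjacency test certifies separation; each cell takes the
minimum over its conflicting pairs (symmetric, deterministic). Radii
floor at 1 px: below centre distances of about 4 px separation is
impossible and disks merge, which mirrors reality — touching cells in
dense cultures are the hard case, and resolving them is delegated to
the peak min-distance, not the mask. Radius 8 puts the background:cell
pixel balance near 20:1 on typical annotated frames (the package
recomputes the exemplar layout — 12 frames of 1196×1596 px with 5878
isolated disks — to a ratio of 18.8), which plain unweighted
cross-entropy handles without class weights.

A 75 % resize of the training images (centre coordinates and disk
radius scaled in the same proportion, 8 → 6) doubles the training set
with smaller cells and narrows the size gap to small-celled target
domains.

## Supervised schedule

Pixel-mean binary cross-entropy; SGD with Nesterov momentum 0.8; batch
size 5; learning rate 0.1 halved after every 10-epoch cycle; 60 epochs
total. One quarter of the images is held out, and the weights of the
epoch with the lowest full-image validation loss are returned. At each
cycle boundary, fresh random patches are cropped at that cycle's patch
size (full-scale default cycle 256², 384², 192², 320², 256², 384²;
desk-scale 64², 96², 48², 80², 64², 96²), with enough patches per image
to cover its area once. Augmentation is applied per patch per epoch:
rotations restricted to right angles plus flips (interpolation-free, so
masks stay exactly binary and geometric transforms apply jointly to
image and mask), uniform crop-offset translation, additive intensity
shift ±10 % of range and Gaussian noise σ = 2 % of range (image only).
Each plane-triplet channel is z-scored per image before entering the
network, identically at train and predict time; the normalization
itself is a package choice, made for robustness to exposure differences
between cultivations.

## Iterative unsupervised domain adaptation

Adaptation assumes the supervised detector transfers to the target
domain with high precision, even at low recall. Each of 6 cycles:

1. Predict heatmaps for 4 randomly drawn unannotated target images
   (re-drawn each cycle; held-out test images are excluded). Detect
   local peaks at threshold 0.2 — deliberately low, to pull weak but
   real detections into the training data — with 5 px minimum
   separation.
2. Dilate the peak points with a radius-6 disk (plain union, no
   shrinking) into pseudo target masks.
3. Assemble a pool of 50 % freshly cropped annotated source patches and
   50 % pseudo-labeled target patches (±1 patch). Source masks are
   never overwritten — this annotated anchor keeps false positives and
   negatives in the pseudo-labels from amplifying over iterations.
4. Train 10 epochs at learning rate 0.1 × 0.5^cycle, switching patch
   size per cycle as in the supervised phase. A quarter of the mixed
   pool is held out to track validation loss; adaptation continues from
   the final weights of each cycle.

No target-domain annotation is ever consulted. Peaks are defined on the
8-neighbourhood with plateau handling: an equal-valued plateau counts
once, contributing its centroid-nearest pixel, and only if no pixel of
the plateau borders a strictly greater value. Min-distance suppression
is greedy by descending peak value (ties by row, then column), with
Euclidean distance. Inference (`detect_cells`) reuses the auto-labeling
peak parameters by default; both are independent config keys.

## Scoring

A detection matches a ground-truth centre when their Euclidean distance
is strictly below 20 px; among multiple candidates only the closest is
accepted. This is implemented as greedy one-to-one assignment over all
candidate pairs in ascending distance order (deterministic and
symmetric; on random small instances it almost always attains the
optimal bipartite cardinality, and where the two differ the greedy
assignment is the defined behaviour). Precision, recall and F1 follow
the standard formulas; degenerate denominators are resolved as: empty
detections and empty truth score 1.0 (perfect empty agreement), empty
one-sided scores 0.

The density profile smooths ground-truth points with unit-mass Gaussian
kernels (σ = 50 px, so the map sums to the cell count when the frame
pads past the cells), splits the map's [min, max] into five equal-width
value bins — equal density *range*, not equal area or count — and
scores each bin: ground-truth cells are binned at their own locations
(recall side), detections at theirs (precision side; a false positive
contributes at the density of where it fired).

## Synthetic data

The generator emulates the one property of brightfield stacks the
method depends on: through-focus appearance. Each cell is a radially
symmetric Gaussian blob with amplitude `contrast · sign · (p −
focus)/half_range` — zero in focus, inverting sign across it — and
width `radius · (1 + 0.3·|p − focus|)`; frames add Gaussian noise
(σ = 0.02 of range) on a 0.5 background and clip to [0, 1]. Two presets
span the easy/hard axis observed across real cell lines: the source
preset (radius 5 ± 0.5 px, contrast 0.35, 15–25 cells per 128×128
frame, ≥ 14 px separation) emulates separately growing high-contrast
cells; the target preset (radius 2 px and contrast 0.175 — 0.4× and
0.5× the source — 25–40 cells in Matérn-style clusters of ~6 with
≥ 6 px separation) emulates dense low-contrast populations whose cells
have no background around them. What the generator does *not* model:
real point-spread optics, phase effects, cell morphology and internal
texture, debris and artifacts, illumination gradients, stacked
(overlapping in z) cells. Passing end-to-end tests therefore
demonstrates that the pipeline's mechanics — learning, transfer in the
high-precision/low-recall regime, pseudo-label bootstrapping — behave
as designed, not that any particular accuracy carries over to real
microscopy.

## Problem sizes and numerical choices

The shipped end-to-end experiment uses 128×128 five-plane stacks,
depth 3 with 8 base filters, 12 source training images (doubled by the
75 % resize), 60 + 60 epochs — sizes chosen so the whole experiment
runs in a few minutes on one CPU core. Desk-scale geometry scales the
pixel-denominated radii in proportion to the cells (mask radius 4,
pseudo radius 3, peak min distance 3), exactly as the 75 % resize
scales radius 8 → 6 at full scale; scale-free parameters (threshold
0.2, matching distance 20 px, the entire learning schedule) are
unchanged. All randomness — placement, noise, splits, crops,
augmentation, initialization, image draws — flows from one seed through
named child streams, so every stage reproduces bit-for-bit in
isolation. Ties are broken deterministically throughout (peak order by
value, then row, then column; matching by distance, then indices).
Degenerate inputs are defined rather than fatal: empty annotation sets
give all-background masks, empty heatmaps give empty detection sets,
all-background mask collections report an infinite class-balance ratio
with a degenerate flag.

## Known limitations

- The numpy network is CPU-bound and intended for desk-scale or
  moderate problems; there is no GPU path and no multi-GPU training.
- Inference requires input sides divisible by 2^depth (no automatic
  padding).
- The exact layer inventory of the original reduced U-Net is not
  public; depth 3 with two-conv blocks is a reconstruction of "one
  level pair removed while keeping symmetry".
- Detection only: no segmentation masks, no tracking, no growth-curve
  fitting.
- The radius-shrink rule guarantees separation only down to ~4 px
  centre distance; closer annotations merge in the target mask.
- Per-image standardization backfires on *cell-free* fields: with no
  cell contrast to dominate the variance, the z-score amplifies sensor
  noise to unit variance and the detector can emit a few spurious peaks
  at the low 0.2 threshold. These spurious peaks are low-confidence
  (well below true detections, which saturate near 1), so a stricter
  inference threshold suppresses them; a fixed affine normalization
  would avoid the effect entirely but give up robustness to exposure
  differences. Fields with at least a handful of cells are unaffected,
  since their defocus contrast dominates the channel variance.
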