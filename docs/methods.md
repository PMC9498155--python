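# Methods

This note records the modeling choices behind `tileseg`, the parameters that
matter, what the synthetic data does and does not establish, and the
numerical conventions a user may need when comparing against other tools.

## Problem setting

Gigapixel H&E-stained whole-slide images are segmented into tumor and normal
tissue by classifying small square tiles and reassembling the per-tile
scores into a per-pixel map. The ground truth is *area-based*: pathologists
mark only regions they are certain about, so (a) training tiles must lie
entirely inside one labeled region, and (b) pixel-level metrics are
restricted to annotated pixels — an unannotated pixel is "unknown", not
negative. A consequence worth remembering when reading scores: a model that
flags tumor outside the annotated regions is not necessarily wrong there,
and only expert review can say.

## Preprocessing

- **Background masking.** A pixel is background iff `min(R,G,B) ≥ t`. The
  default `t = 220` (8-bit) was chosen once as a conservative setting for
  bright-field scans, where the glass background is near-white in all three
  channels; it is configurable and has no other role in the pipeline.
- **Downsampling** is area averaging over `f × f` blocks (partial edge
  blocks use their true pixel count), rounded to nearest with ties to even.
  Output dimensions are `ceil(H/f) × ceil(W/f)`. Annotations are stored at
  native resolution and divided by `f` when paired with a downsampled
  slide; the pixel-center rasterization of a scaled polygon is then an
  approximation of the scaled mask, exact for axis-aligned rectangles whose
  corners scale onto pixel centers.
- **Rasterization** uses the pixel-center even-odd rule with boundary pixels
  included (delegated to a robust geometry library). Interior rings are
  holes. Tumor/normal polygon pairs with overlapping interiors are rejected
  with the offending pair indices.

## Tile extraction and splitting

Tiles are 128 × 128 px on a grid anchored at the slide origin (anchoring is
a reproducibility choice; nothing in the method depends on it). The
"fully inside" rule — every pixel of the tile in one label's mask — follows
from the certainty semantics of area-based annotation; a majority-label rule
would dilute it. With stride = tile size the footprints are disjoint, which
keeps training patches independent. Class balancing is by uniform
undersampling of the majority class (the alternative, loss weighting, would
entangle the balance with the optimizer; undersampling keeps the training
set interpretable). Splits are 70/10/20 *by slide* — validation/test counts
are the fractions rounded to nearest, training takes the remainder — so a
slide's tissue never appears in two splits.

## The classifier

Architecture (input `128 × 128 × 3`, intensities scaled to [0, 1]):

| block | conv | after |
|---|---|---|
| 1 | 8 filters, 3×3 | batch norm → SELU → 2×2 max pool |
| 2 | 16 filters, 3×3 | batch norm → SELU → 2×2 max pool |
| 3 | 16 filters, 5×5 | batch norm → SELU → 2×2 max pool |
| 4 | 32 filters, 3×3 | batch norm → SELU → 2×2 max pool |
| head | global average pool → dense 32→2 → softmax | |

The spatial-reduction layout between conv layers is a design decision: 2×2
max pooling after every block plus global average pooling is the smallest
standard layout consistent with a tiny dense head. Batch-norm statistics
are frozen at inference, so prediction is deterministic and batch-size
independent (batched and one-by-one evaluation agree to float32 precision).

Training: SGD with momentum 0.75, learning rate 1e-4, L2 penalty 1e-4
(coefficient a default; only weights are penalized, not batch-norm
parameters or biases), batch size 64, loss = mean squared error of the
softmax tumor probability against the 0/1 label. A stratified 10% holdout
of the training patches monitors validation loss; training stops when that
loss has not improved for `patience` epochs (default 2) and the best-epoch
weights are restored. The nominal 0.5 threshold is used only for
training-time accuracy; the deployed threshold comes from the sweep.

**Desk-scale training.** The reference recipe assumes order 10⁵ patches and
thousands of SGD steps per epoch. Test-size synthetic cohorts provide
order 10² patches, so the tests and the end-to-end acceptance run raise the
learning rate (3e-2 at 128 px tiles, 0.1 at 32 px) and lengthen patience
(8–25 epochs, since one epoch is only one or two batches and the momentum
transient spans several). These are step-count compensations decided from
the batch arithmetic, not tuned values; everything else (architecture,
momentum, batch size, loss, early stopping) is unchanged.

The implementation is pure numpy: im2col convolutions backed by BLAS
matmuls, the input-gradient computed as a same-padded convolution with the
spatially flipped kernel, and max-pool gradients split equally among tied
maxima so gradient mass is conserved. Analytic gradients are verified
against central finite differences in the test suite. One conv bias per
layer exists but is analytically cancelled by the following batch norm; it
is kept for shape symmetry and its gradient is ~0.

## Sliding-window segmentation

Anchors lie at multiples of the step; when the last multiple does not reach
the border, one extra anchor flush with the border is appended per axis, so
every pixel is covered (border pixels average over fewer windows — border
policy is a design decision, as is everything about margins). For step `s`
dividing the window `w`, interior pixels are covered by exactly `(w/s)²`
windows: 1, 4, 16, 64, 256 for steps 128…8. Aggregation accumulates a sum
array and a count array and divides once at the end — algebraically equal
to storing all per-pixel predictions, but in O(HW) memory; the test suite
checks exact agreement (≤1e-9) with a naive double loop. Binarization
happens *after* averaging, with `mean ≥ t ⇒ tumor` (ties to tumor — for a
diagnostic aid a false alarm is cheaper than a miss). Uncovered pixels
carry the sentinel −1 in stored maps, are excluded from metrics, and render
in magenta.

## Threshold and step-size selection

The threshold sweep evaluates f1 on validation-patch confidences at every
multiple of 0.01 in [0, 1] and keeps the best; among ties the lowest
threshold wins (sensitivity-favoring). The swept threshold is then reused
for pixel-level binarization. The step-size trade-off table reports
macro-averaged pixel metrics (mean ± sd over slides) and wall-clock times
per step; times are informational only and never asserted. On easy
synthetic data the sweep typically selects a very low threshold because all
validation confidences separate cleanly; on real data the optimum sits
between the classes' confidence distributions (e.g. well below 0.5 when
tumor confidences are compressed upward).

## Synthetic slides

Each slide is a white canvas with non-overlapping axis-aligned rectangular
regions; a region is a cytoplasm-colored field with per-pixel Gaussian
color jitter (sd 8) and Poisson-placed disc nuclei. Tumor regions emulate
hypercellularity: 12 nuclei / 1000 px² of radius 3–6 px in dark purple on a
mauve field, versus 3 / 1000 px² of radius 2–4 px on a light pink field for
normal tissue. Region polygons pass through corner pixel centers, so
rasterization reproduces the painted rectangle exactly. All randomness
flows through one seeded generator per slide; cohorts derive per-slide
seeds from a master seed. Default canvas 1024 × 1536 px — a desk-scale
stand-in for ~29,000 × 17,000 px clinical scans.

What a green test on this data establishes: the pipeline's plumbing and the
classifier's ability to learn separable local texture. What it does not:
robustness to stain variation, tissue-architecture cues, ambiguous
boundaries, scanner artifacts, or any clinical performance claim. With
identical textures for both classes the end-to-end test verifies the
negative control: held-out patch AUROC is consistent with chance. (At desk
scale that AUROC is measured on ~50–100 disjoint patches, so "chance" means
within sampling noise of 0.5, not 0.5 exactly.)

The default multi-resolution factors (4, 6, 8) mirror full-scale practice;
at desk scale they would shrink a synthetic slide below one tile, so
desk-scale configurations use factor 1 explicitly.

## Numerical conventions

- Coordinates are 0-based `(row, col)`; annotation vertices are `(x, y)` as
  GeoJSON dictates, converted on read.
- Rounding is nearest-with-ties-to-even everywhere an 8-bit value is
  produced (downsampling, rendering: confidence 0.5 → gray 128).
- f1 is reported as 0 with a warning when precision + recall = 0; AUROC is
  NaN with a warning for single-class label sets.
- Confidence maps are float32 TIFF on disk; masks 0/255 PNG; model weights
  npz plus a JSON sidecar with the full configuration and seeds.

## Known limitations

- No pyramidal WSI container support (SVS/NDPI): rasters must fit in memory
  as flat arrays.
- No stain normalization or augmentation; the classifier sees raw RGB.
- The numpy training loop is single-threaded BLAS-bound; it is sized for
  10²–10³ patches, not 10⁵ (a framework backend would be needed for
  full-scale training).
- Per-slide macro averages treat every slide equally regardless of its
  annotated area; pooled metrics are exposed alongside for the other view.
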