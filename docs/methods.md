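# Methods

## Problem setting

An *in vitro* osteoclast differentiation assay produces brightfield images of
TRAP-stained cultures (nominally 1920×1440 px at 1.32 px/µm, i.e. a
1.587 mm² field). Osteoclasts are operationally defined as TRAP-positive
(pink/purple) cells with more than three nuclei; everything else is a
non-osteoclast. The pipeline counts osteoclasts per image and per well
without any manual marking.

## Segmentation

Stages, in order, with their parameters (all in `SegmentationConfig`):

| parameter | default | note |
|---|---|---|
| grayscale | luma 0.299R+0.587G+0.114B | half-up rounded to 8-bit |
| binarization | Otsu on the 256-bin histogram | smallest maximizing threshold on ties; foreground = intensities ≤ t\* (`dark_cells` polarity; a `bright_cells` flag inverts) |
| morphology | 3×3 square; opening ×2 then closing ×1 | iteration counts follow the canonical marker-watershed recipe and are config-exposed |
| distance transform | exact Euclidean | the image border is treated as adjacent to virtual background so the map is defined on all-foreground masks |
| markers | pixels with D ≥ 0.7·max D | 8-connected components, labeled 2…; sure background = complement of the mask dilated ×3, labeled 1 |
| watershed | flood of −D from the markers | boundary pixels labeled −1 |
| size filter | drop segments with area < 500 px | strictly less than: a 500-px segment is kept |
| crops | 50×50 px around each centroid | centroid = per-axis pixel mean, half-up; borders filled by edge reflection (zero-padding would inject artificial dark corners into the classifier's input) |

**Marker scope.** `marker_scope` selects the reference for the 0.7 fraction:
`"component"` (default) thresholds each mask component at 0.7 of *its own*
distance maximum; `"image"` uses the whole-image maximum. The image-global
rule is only usable when all cells have similar size: any cell whose
interior depth is below 0.7 of the largest cell's radius receives no marker
and is flooded by the background, so on fields mixing 40-px osteoclasts with
15-px mononuclear cells it loses most small cells (a dedicated test
demonstrates this). The per-component rule gives every detected component at
least one marker, while still splitting touching cells (a merged pair has
two superlevel components because the neck depth of two touching convex
bodies falls below 0.7 of the peak depth). Both failure modes of the global
rule — small-cell loss and large-cell shattering into sub-500-px pieces that
the size filter then discards — are reproducible by setting
`marker_scope="image"`.

**Flooding surface.** The watershed floods the negative distance map, the
canonical distance-based marker watershed: it splits touching same-colored
cells at the neck, where a color-gradient surface has no ridge. The
standalone `watershed_segment()` falls back to the Sobel gradient of the
grayscale image when no distance map is supplied.

**Connectivity and ties.** Marker components use 8-connectivity; flooding
uses the watershed implementation's default 4-connectivity, and watershed
lines between two background basins are relabeled as background.

## Classification

Crops are z-scored per channel with μ, σ pooled over all training-crop
pixels and frozen for validation/test/inference; σ is floored at ε = 10⁻⁶ so
degenerate constant channels normalize to zero rather than overflow.

Two architectures share one NumPy layer stack (convolution via im2col,
batch normalization, ReLU, max/global-average pooling, residual blocks,
linear softmax head; backpropagation is verified against finite differences
in the test suite):

* `resnet18` — the full profile: 7×7/stride-2 stem into 64 maps, 3×3
  max-pool, four two-block residual stages of width 64/128/256/512, global
  average pooling, fully connected softmax head; intended pairing: batch
  256, 500 epochs.
* `small` (default) — the desk profile for CPU-scale runs: 3×3 stem into 16
  maps, 2×2 max-pool, two residual stages of width 16/32; batch 64,
  20 epochs. Same optimizer settings as the full profile.

Training: Adam (lr 0.002, L2 10⁻⁵ added to the gradient), cross-entropy,
one randomly chosen augmentation per sample per epoch from a 12-transform
pool (rotate ±30°, shear-x/y ±0.3, translate-x/y ±10 px, color/brightness/
contrast/sharpness enhancement ±0.9, posterize 4–8 bits, solarize threshold
0–256, autocontrast — the AutoAugment operation set; every magnitude range
sits in `AugmentationSpec` so it can be changed without code edits). After
every optimizer step the teacher parameters (and batch-norm running
statistics) are updated as θₜ = αₜθₜ₋₁ + (1−αₜ)θ′ₜ with
αₜ = min(0.999, 1 − 1/(t+1)) — the standard mean-teacher ramp; without it a
teacher started from random weights cannot converge within a few hundred
steps. The teacher snapshot with the highest validation accuracy (earliest
epoch on ties) is returned and used for all inference. Checkpoints store
parameters, batch-norm buffers, channel statistics, the architecture tag, a
config hash and a format version in one archive, and round-trip
bit-identically.

Data splits are always made at the whole-image level, never at the crop
level, so no field of view contributes crops to two splits. The synthetic
training corpus is built from scenes with equal osteoclast and
non-osteoclast counts (≈1:1 crop balance); no class weighting is applied.

## Synthetic scenes

`generate_scene` renders, on a light gray background (level 240), three
object classes as jittered ellipses (random orientation, eccentricity
±0.25, boundary modulation of amplitude 0.04 with 4–6 lobes):

* **osteoclasts** — radius 20–45 px (body ≥ 500 px by construction), 3–8
  darker interior nuclei, saturated pink/purple body;
* **non-osteoclasts** — radius 6–14 px by default, 0–2 nuclei, pale pink
  body; many default-sized bodies fall below 500 px and are removed by the
  size filter, as in real cultures. The end-to-end count/detection studies
  use radius 14–17 px so that every body clears the filter and each cell
  should yield exactly one retained segment;
* **debris** — radius 2.5–9 px, area < 500 px enforced, dull gray-brown.

Body green is sampled as R minus a class-specific red–green gap (osteoclast
75–105, non-osteoclast 40–60, disjoint by 15 levels), so the stain
saturation separates the classes *by construction*; the palest body stays
≥ ~2.5 noise SDs below the Otsu threshold so binarization never fragments a
cell. Bodies are kept near-convex deliberately: the distance transform of a
convex body is concave, hence its 0.7-superlevel set is connected and the
marker rule yields exactly one marker per non-touching cell. Gaussian pixel
noise (SD 5/255) is added and clipped to 8-bit. Placement enforces
center-to-center spacing ≥ sum of max radii + 8 px ("non-touching"); a
`touching_pairs` mode instead places two osteoclasts at 0.75× that distance
to exercise watershed splitting. Placement, shapes/colors, debris and noise
draw from four independent substreams of one seed, so changing `n_debris`
does not reshuffle cell placement, and scenes are bit-reproducible.

What the generator does **not** emulate: stain texture and vesicle
structure, out-of-focus blur, uneven illumination, overlapping (not merely
touching) cells, and the long tail of real osteoclast morphologies. Passing
tests therefore demonstrate that the pipeline's machinery is correct and
self-consistent, not that the shipped defaults reach any particular accuracy
on real cultures.

## Evaluation accounting

A ground-truth center counts as detected iff it lies on a pixel of a
retained segment (centers are the only manual annotation; no masks exist).
If one segment contains k centers, one is detected and k−1 are missed — an
under-split cluster is a detection failure. Retained segments containing no
center are spurious. Detection rates aggregate two ways: `pooled`
(Σdetected/Σtotal) and `macro` (mean of per-image rates); both are reported
because they differ when image sizes differ. Classification rates are
emitted relative to segmented cells and, when the full annotated totals are
supplied, relative to all cells; undefined rates (zero denominators)
propagate as explicit `None`, never as 0. A radius-based matching fallback
was considered and rejected: center-inside-segment is parameter-free and
matches how the annotations were made.

## Counting and normalization

Per-image counts are the classifier's osteoclast tallies (not
area-weighted). Per-well count = mean per-image count × well area / field
area, defaults 95.0 mm² and 1.587 mm² (nine fields per well). The printed
field dimensions (1,451.11 × 1,088.33 µm) and the printed area (1.587 mm²)
are mutually inconsistent at full precision; the pixel scale (1.32 px/µm) is
the single source of truth, and 1920×1440 px at that scale reproduces
1.587 mm² to three decimals.

## Desk-scale study conditions

The end-to-end suite and `scripts/acceptance.py` use: 20 counting scenes of
512×512 px with 5 osteoclasts + 20 non-osteoclasts + 3 debris each
(500 cells total); a training corpus of 125 scenes of 640×640 px with
10 + 10 cells (2,000 training / 250 validation / 260 test crops after an
80/10/10 image-level split); the `small` architecture for 20 epochs at
batch 64. These sizes keep a full run to a few CPU-minutes while leaving
every stage's statistics meaningful (hundreds of cells per estimate).

## Known limitations

* The classifier is NumPy-based and CPU-bound; the full `resnet18`/500-epoch
  profile is implemented but slow, and is not exercised by the test suite.
* The marker rule (either scope) can still shatter strongly non-convex
  cells; the 500-px filter usually rescues exactly one piece, but a cell all
  of whose pieces are small is lost.
* Otsu binarization assumes a bimodal histogram; on fields that are almost
  entirely confluent or entirely empty the threshold is unreliable (a
  constant image raises an explicit degenerate-histogram error).
* Synthetic colors are chosen for separability and stain plausibility, not
  histological fidelity; no quantitative TRAP color model exists.
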