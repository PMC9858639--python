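# Methods

This note records the models, conventions and design choices behind
woundkit, in the order the pipeline runs.

## Chart model and rendering

The chart is modelled in physical millimetres with the origin at its
top-left corner. Defaults: 75 × 35 mm card, four 12.7 mm fiducial markers
at the corners (1 mm edge margin), twenty-four 6.35 mm color patches in a
6 × 4 grid with 1 mm gaps, centred in the rectangle spanned horizontally
by the inner marker edges and vertically by the card. The inter-element
margins are not standardised anywhere, so they are package choices,
recorded in `ChartGroundTruth.margins_mm` so downstream code never
hard-codes them.

Rasterisation samples each pixel at its centre: pixel `[r, c]` covers the
point `((c+0.5)/px_per_mm, (r+0.5)/px_per_mm)` mm. This makes ground
truth exact (corner at mm position *x* is at pixel coordinate
`x·px_per_mm`), bit-stable, and linear in resolution. Rendering refuses
`px_per_mm < 2` or marker modules under 2 px, where decoding becomes
unreliable.

Reference colors are the published ColorChecker-Classic sRGB values,
exposed as data (`ReferencePalette`) so a measured palette for a specific
print batch can be substituted.

## Fiducial markers

Markers are ArUco-style: a one-module black border around a 4 × 4 binary
identity matrix (6 × 6 modules total). The package defines its own
four-marker dictionary whose patterns differ by at least 6 bits under
every relative rotation, including self-rotations, so identity and
orientation decode unambiguously with sampling-noise margin; a test
enforces these distances. IDs (0, 1, 2, 3) map to corners (TL, TR, BR,
BL), and patch order is row-major starting adjacent to marker 0.

Detection: dark connected components (global Otsu, with a local-threshold
fallback) are filtered by size/solidity; each candidate's outer boundary
is traced at sub-pixel precision by contour extraction at the midpoint
between ink and background intensity; the contour is rolled to start at
its farthest-from-centroid point (a true corner of a convex quad) and
reduced to four vertices by Douglas–Peucker with escalating tolerance;
corners are refined by total-least-squares line fits to each edge
(corner-adjacent points trimmed) intersected pairwise. Cells are then
sampled through the quad's projective map and matched against the
dictionary in all four rotations. On clean renders corner error is ≈0 px
at 10 px/mm and ≤0.7 px down to 2 px/mm; a known projective warp is
recovered to <0.5 px reprojection over all 16 corners.

## Calibration

* **Homography, not pose.** The chart→image map is estimated as a full
  3 × 3 homography from the 16 marker corners (normalised DLT). A
  homography subsumes the frontal case and handles oblique charts; for
  out-of-plane wounds the scale remains a chart-plane approximation.
* **Patch sampling** averages a 7 × 7 lattice over the central 40 % of
  each patch side, projected through the homography — wide enough to
  average noise, narrow enough to avoid edge bleed. Any window leaving
  the frame raises an error naming the patch.
* **Color transform.** A pure 3 × 3 linear map fitted by pseudo-inverse
  in device 8-bit RGB (no gamma linearisation, no intercept), applied to
  RGB row vectors and clipped to [0, 255]. An affine 3 × 4 variant is
  available via `intercept=True`. Rank-deficient patch matrices raise.
  The fit residual (RMS over the 24 patches) is reported as a quality
  diagnostic.
* **Scale** is the mean of `marker_side_mm / projected side` over all 16
  marker sides (4 markers × 4 sides). Marker corners are sub-pixel while
  patch edges are not, so markers, not patches, carry the measurement.
* **Missing markers are a hard error** listing the missing IDs: a partial
  calibration would silently corrupt downstream mm² values.

A linear cast is only recoverable if it keeps colors in gamut — once a
channel clips at 0/255 the information is destroyed before fitting. The
synthetic cast generator therefore draws white-balance-like perturbations
of the identity and shrinks them until the reference palette stays within
[2, 253]; under such casts the round-trip error is ≤2 counts per channel
(≤1 noise-free) and corrected-vs-reference correlation exceeds 0.999.

## Synthetic scenes

Each scene emulates the structure, not the photorealism, of a clinical
wound photograph on one 8-bit RGB frame (default 256 × 256 px at
2 px/mm):

* **Wound boundary**: a low-order Fourier perturbation of an ellipse,
  `r(θ) = R·(1 + Σ_{k=2..5} a_k cos(kθ+φ_k))`, `a_k ~ N(0, 0.06/√k)` —
  smooth, closed, irregular.
* **Tissue partition** with exact per-class pixel counts: the epithelial
  fraction occupies the pixels closest to the wound boundary (epithelium
  advances from the edge); the necrotic fraction forms compact blobs
  around a few seeds (characteristic patch ≈40 mm², keeping necrosis
  small and rare as in clinical data); granulation fills the rest.
  Default mixture (epithelial, granulation, necrotic) = (0.25, 0.65,
  0.10) of the wound area. Classes are mutually exclusive and confined
  to the wound mask.
* **Colors**: truncated Gaussians around class-characteristic means —
  granulation beefy red (178, 48, 52), epithelial deep pink (226, 130,
  148), necrotic dark yellow-brown (97, 74, 42), skin (198, 152, 124)
  with smooth mottling. These follow the qualitative clinical
  descriptions of each tissue; the spreads (8–12 counts) keep classes
  separable but overlapping.
* **Chart** composited frontally at a known origin; wound-chart overlap
  is a placement error. **Cast + noise**: an invertible 3 × 3 matrix and
  additive Gaussian noise (σ = 3) applied to the whole frame; ground
  truth is retained pre-cast.

Cohorts assign each subject a fixed boundary shape and a per-visit radius
contraction factor drawn from U(0.88, 0.92), so ground-truth wound area
is strictly decreasing across visits; necrosis recedes and
epithelialisation advances linearly over visits. Everything derives from
one `SeedSequence`, so a fixed seed reproduces scenes byte-for-byte.

What passing on these scenes does *not* show: robustness to specular
highlights, shadows and illumination gradients, out-of-plane wound
curvature, motion blur, occluded or bent charts, or tissue appearance
beyond color/position statistics. Results on synthetic cohorts bound the
pipeline's correctness, not its clinical accuracy.

## Network and training

The layer library (convolution, depthwise convolution, batch norm,
ReLU6, nearest upsampling, weighted softmax cross-entropy, Adam with
L2-coupled weight decay) is written on numpy with explicit backward
passes, each verified against central finite differences to <10⁻⁶.
Float64 and one CPU thread make runs bit-reproducible for a fixed seed.

The model is U-shaped with one shared decoder and two 1×1 heads (2-class
wound, 4-class tissue). MBConv blocks are expand(1×1)–depthwise(3×3)–
squeeze(1×1) with identity shortcuts where shapes allow; no
squeeze-and-excitation. Stage layouts: a MobileNetV2-style plan
(t=1/6, channels 16→320, 7 stages, ≈3.2 M parameters here) and an
EfficientNet-B2-style plan (width 1.1/depth 1.2 scaling of the base
layout, channels 16→352, ≈7.3 M), both with stride-2 stems and 32×
total downsampling; and `tiny_test` (stride-1 stem, two stride-2 MBConv
levels, ≤32 channels, ≈12 k parameters) for CPU-scale experiments.
Encoders are randomly initialised (He); no pretraining.

Training: Adam lr 10⁻³, weight decay 10⁻⁴, batch 4, pixel-wise weighted
cross entropy `mean(−w[y]·log p[y])` summed over branches, with class
weights defaulting to inverse pixel frequency on the training fold
(normalised to mean 1, clipped to [0.25, 8] for stability). The
checkpoint with the lowest validation loss is kept. Augmentation:
random crop, horizontal/vertical flips, grid distortion (displaced
4 × 4 control lattice, bilinear for the image, nearest for masks),
brightness, contrast, Gaussian noise; geometric ops are shared between
image and masks. Non-square inputs are normalised by scaling the shorter
side to the resize target and centre-cropping.

At inference, ties at the argmax resolve to the lowest class index.
Tissue labels are reported raw and additionally masked by the wound
branch (`tissue_labels_in_wound`), since nothing forces the two branches
to agree.

## Evaluation conventions

* IoU 0/0 (class absent from prediction *and* truth) returns 1.0 and is
  flagged (`both_empty`); summaries excluding such images are also
  emitted (`mean_iou_present_only`). Penalising correct absence would
  misrank models on necrosis-free images.
* Summary SDs are across images (population SD); a per-fold breakdown is
  emitted alongside when a fold plan is supplied.
* Nested CV splits subjects, not images: outer folds partition subjects
  into near-equal test sets (sizes differ by ≤1), inner folds partition
  each outer fold's remaining subjects into validation sets. Splits are
  deterministic in the seed.
* Inter-rater agreement is per-pair, per-class mean ± SD of per-image
  IoU; the overall per-class figure is the unweighted mean over pairs.
  Images missing an annotation are excluded with a warning and counted.

## Measurement

`area = pixels × mm_per_px²` in the chart plane; planar, no curvature
correction. Longitudinal series are sorted by visit with per-class first
differences and a trend flag (decreasing / increasing / mixed /
single-visit). Duplicate visit indices are an error.

## Problem sizes used in tests

Experiments run at desk scale: 16 scenes of 128 × 128 px (2 px/mm,
chartless for the recovery run; 256 × 256 with chart and a fixed
wound-centred 128 px crop for the calibration-benefit run), the
`tiny_test` encoder, 15 epochs, batch 4; the flip-consistency property
uses a 40-epoch run of the same recipe, and the calibration-benefit
comparison averages 3 seeds. The default chart cannot fit a 128 px frame
at a decodable resolution, which is why recovery scenes omit it and the
benefit run calibrates full frames before cropping. These sizes are the
package's chosen study conditions for CPU reproducibility; the
architecture and recipe scale unchanged to 1024 px inputs and the
paper-style encoders.

## Known limitations

* Scale estimates are valid only in the chart plane; wounds on curved or
  oblique surfaces are measured approximately.
* The color transform is global and linear: spatially varying
  illumination, specular clipping and strong gamma effects are out of
  model (the fit residual exposes them).
* Marker detection assumes the chart is fully visible, roughly in focus
  and darker than its background; occlusion recovery is not attempted.
* The numpy network trains small models quickly but is not suited to
  GPU-scale training; the architecture definitions are, by design,
  framework-portable.
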