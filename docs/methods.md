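# Methods

## Problem setting and conventions

The package localizes the cutting point for robotic harvesting of
edible flowers from a single bench-top RGB-D view.  The camera looks
down at the crop; its frame is +X right, +Y down, +Z forward into the
canopy.  Clouds are *organized*: one 3D point per pixel of the aligned
RGB image, with an all-NaN triple marking invalid depth.  Pixels are
0-based, u = column, v = row; boxes half-open.  Clouds are in meters;
all morphometry and calibration is in millimeters, and the single m→mm
conversion happens where the two meet (diameter and pluck-point
computation).  At the sensor's 1280×720 resolution a frame carries
921,600 cloud points.

Detection and segmentation are *not* performed here: boxes and masks
produced by external deep models arrive through files (YOLO-format
text or COCO JSON; 8-bit PNG masks named `<frame_id>_det<k>.png`).  A
classical HSV-threshold blob detector (two-interval union for hue
wrap, 8-connected components, area filter) is included so the
geometric pipeline can be driven without any learned model.

## Mask cleaning and occlusion handling

Box-prompted zero-shot masks often contain several disconnected
polygons of which only one is the prompted flower.  `clean_mask` keeps
the 8-connected component whose pixel centroid is nearest the box
center (ties: larger area, then input order).  The centroid — not the
component's bounding-box center — is used because it is robust for
concave components.

Overlap handling follows the harvesting logic that an occluded flower
is simply picked on a later pass.  A mask is flagged `occluded` iff its
binary dilation by `min_gap_px` (default 3 px) intersects another mask
*and* its mean depth is larger, i.e. it lies beneath.  Exactly the
deeper of an overlapping pair is skipped.  This dilation-plus-depth
rule is one concrete operationalization of "only flowers with a
complete point cloud are processed"; alternatives (visibility ratios,
contour completeness) would need ground truth we do not have, and the
rule is configurable.

## Pose by PCA

The cleaned mask indexes the organized cloud; NaN points are dropped
and counted, never interpolated.  The pose is the eigen-decomposition
of the 3×3 covariance of the mean-centered points (tests assert
agreement with the SVD route): orthonormal axes e₁,e₂,e₃ with
λ₁ ≥ λ₂ ≥ λ₃.  For a disk- or dome-like corolla the stem direction is
the *surface normal*, i.e. the minimum-variance axis, so
`main_axis_rule="min_variance"` (e₃) is the default; `max_variance`
(e₁) is selectable for elongated targets.  The main axis is
sign-normalized to u·ẑ ≥ 0 so it points stem-ward for a downward
camera; an exactly horizontal axis gets its first nonzero component
made positive for determinism.  Fewer than 3 finite points raises
"insufficient depth"; a collinear cloud (two vanishing eigenvalues)
raises "degenerate geometry" — the pipeline maps both to per-flower
statuses.

## Morphometry

Points are projected onto the plane orthogonal to the main axis
through the centroid, so the diameter is measured in the flower's own
plane and is invariant to rigid motion — this avoids assuming camera
intrinsics to convert pixels to mm.  The diameter is the maximum
pairwise distance of the convex-hull vertices (caliper width), which
matches what a hand-held caliper measures; twice the inscribed-circle
radius is available as `method="inscribed"`.  When the projected
points are collinear the max pairwise distance is still well defined
and is returned; only fewer than two distinct points is an error.

The polygon center is the Chebyshev center — the in-polygon point
maximizing distance to the boundary — solved as the standard linear
program max r s.t. aᵢ·x + r‖aᵢ‖ ≤ bᵢ over the edge half-planes
(scipy HiGHS).  Tests check it against a dense-grid brute-force
maximizer and an independent geometric library implementation.

The flower's 3D center combines the Chebyshev center of the mask's
pixel hull (sub-pixel u,v) with a depth taken from the *top* of the
flower: the mean z of the smallest-z decile of the flower's points.
The decile makes the estimate robust to single-pixel depth outliers;
the point is placed exactly on the pixel's viewing ray by rescaling
the nearest cloud point to the top depth.  If no finite point lies
within 10 px of the center pixel the flower is flagged `no_depth`.

A known limitation, quantified in testing: the top-decile depth rule
assumes the flower's top coincides with its center, which is exact for
upright or domed flowers but biased by ≈ r·sin(tilt) for a strongly
tilted *flat* disk (the "top points" are then the near rim).  The
noiseless consistency checks therefore use upright synthetic flowers;
tilted flowers (up to 15°) are exercised in the noisy end-to-end
recovery metric, where the dome keeps the bias small.

## Plucking-point calibration

Per species, ordinary least squares fits h = a·d + b on a seeded
random 80% of the caliper measurements (d = corolla diameter, h = top
of flower to the cut, both mm); the held-out 20% is kept for
evaluation.  The fit is delegated to scikit-learn's `LinearRegression`
and verified against closed-form normal equations to 1e-12.

Because overestimating h merely cuts a little lower on the stem while
underestimating it damages the flower, inference uses a parallel
*upper-boundary* line h = a·d + b + c.  The default offset c is the
one-sided empirical quantile of the training residuals — the order
statistic r₍ₖ₎ with k = ⌈coverage·n⌉ — which guarantees at least the
requested coverage (default 85%) on the training set by construction;
`normal_theory` (c = z(coverage)·residual SD, 2 dof removed) is the
parametric alternative.  On held-out Gaussian data the under-cut rate
is ≈ 1 − coverage, which the tests verify within binomial error.  The
published three-species coefficient table ships as package data and is
user-overridable by a CSV of the same schema; the packaged rows carry
no residuals, so boundaries cannot be re-derived from them — they are
used as-is.  The two pansy varieties are pooled as one species.

## Synthetic scenes

Flowers are spherical caps: base diameter d, dome height (default
3 mm; 0 gives a flat disk), apex = flower center, cap normal = main
axis (+Z-leaning, tilt drawn uniformly up to 15° by default),
placed on a jittered non-overlapping grid at bench depth 0.5 m.
Species diameters are uniform in caliper-realistic ranges centered on
28 mm (snapdragon) and 36 mm (marigold), with a right-tailed
two-component mixture up to 60 mm for pansy.  The default camera is a
1280×720 pinhole with 700 px focal length and centered principal point
(≈ 0.71 mm per pixel at 0.5 m); smaller grids with the *same angular
resolution* are used in tests to keep runtimes short.

Rendering is exact ray casting: each pixel's cloud point is the
analytic ray-cap intersection on that pixel's ray, z-buffered across
flowers, with a background plane elsewhere — so back-projection
round-trips to the pixel center and the deeper flower of an
overlapping pair loses exactly the shared pixels (which is what the
occlusion flagger must detect).  Sensor noise is Gaussian *depth*
noise applied along the ray: stereo depth errors are along the viewing
direction, while lateral position comes from the pixel grid.  The
generator does not attempt photorealism, petals, stems or leaves; what
passing tests show is that the geometry and calibration chain is
correct and noise-stable on idealized corollas, not that any
particular detector segments real flowers well.

Measurement tables emulate the calibration campaign: 100 flowers per
species (300 total) with h = a·d + b + N(0, σ), σ = 8 mm by default,
around the packaged per-species lines; a non-positive draw (≈0.1% of
cases at the smallest diameters) is replaced by the linear mean.  All
generators are bit-reproducible under a fixed seed.

## Numerical choices and test conditions

* Eigenvalues are clipped at 0; rank deficiency is declared below a
  1e-12 relative eigenvalue ratio.
* The Chebyshev LP reports the HiGHS optimum; under ties (e.g. a
  rectangle) any point of the optimal segment is a valid center.
* Component selection ties break by area then index; occlusion ties
  (equal mean depth) keep both flowers.
* The YOLO dialect is `class cx cy w h [conf]`, normalized, half-open
  pixel corners after conversion; COCO boxes are absolute x,y,w,h.
* End-to-end accuracy is measured on 640×480 frames at sensor angular
  resolution, 5 flowers per scene: median plucking-point error is
  ≈ 0.3 mm noiseless/upright and ≈ 1.6 mm at σ = 1 mm depth noise
  with 15° tilts and 3 mm domes (the acceptance script recomputes
  these), against a ≤ 5 mm budget chosen as a small fraction of stem
  length.
* Per-flower failures are statuses (`occluded_skipped`, `no_depth`,
  `degenerate`), never exceptions, so a frame is always fully
  processed; only a missing species calibration aborts a run, before
  processing starts.

## Known limitations

* Whether a leaning snapdragon's PCA main axis tracks the stem or the
  corolla face cannot be settled without robot trials; `max_variance`
  is exposed for elongated poses.
* The packaged boundary offsets were estimated on a measurement
  campaign whose raw data is not distributed; with user measurements
  the `calibrate` command re-derives both lines.
* The occlusion rule uses mean mask depth; interleaved flowers at
  nearly equal depth may both be kept.
* Diameter from the max caliper width is slightly inflated by heavy
  *lateral* noise; the sensor model here (depth-only noise) does not
  exercise that regime.
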