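# Methods

## Scope and data model

`canopy3d` processes one scanning pass over a row of field plots. The raw
record is a *session*: per-frame 16-bit depth PNGs in millimeters (0 = no
return), 8-bit color PNGs registered to the depth grid, and `gps.csv` with
one fix per frame. The pipeline's universal currency is the colorized point
cloud (N×3 float64 meters + N×3 uint8 RGB); plots are the unit of analysis.
Depth–color registration and sensor drivers are out of scope — frames are
assumed registered on arrival.

## Coordinates

GPS fixes are projected to UTM (WGS84) with Krueger's transverse-Mercator
series in the third flattening to sixth order; round-trip error is far below
a millimeter anywhere inside a zone, which the tests verify against an
independent series implementation. Zone exceptions around Norway/Svalbard
are not applied (irrelevant at crop-field scale).

Each plot uses a local frame: y along travel, x across-row, z up. The travel
direction is the principal axis of the easting/northing scatter (total least
squares, so jitter in both coordinates is treated symmetrically), oriented
from the first toward the last fix; the rotation angle from grid north gets
the sign that maps travel to +y. Altitude deltas pass through unchanged
(no smoothing) as local z.

## Reconstruction

* **Back-projection.** Pinhole model per valid pixel, X = (u−c_x)·d/f_x,
  Y = (v−c_y)·d/f_y, z = H_cam − d. Pixels with d = 0 or d > H_cam + 5 cm
  are dropped. Intrinsics are configuration, defaulting to a
  Kinect-v2-class depth sensor (512×424, f ≈ 365 px); H_cam defaults to
  2.4 m.
* **Region of interest.** Per frame: x ∈ ±W/2 with W = 1.52 m (the row
  spacing / sensor enclosure width), y spanning half the gap to each
  neighboring acquisition, z ∈ [0, H_cam]. The first and last frames of a
  plot have no neighbor on one side; the plot's median inter-frame gap is
  substituted so coverage stays contiguous without extrapolating GPS.
* **Ground leveling.** MLESAC plane fit: 500 three-point hypotheses scored
  by the truncated quadratic min(r², T²), T = 1.96σ with σ = 0.02 m, seeded
  RNG, followed by an SVD least-squares refit on the inliers and one
  re-estimation pass. The fit is rejected (and no rotation applied) when
  the inlier fraction is below 0.2 or the normal tilts more than 15° from
  vertical — full vegetation cover has no visible ground, and the ground is
  then assumed level. The correction splits the detected normal's tilt into
  its X-Z and Y-Z projections, removed by a rotation about y then about x;
  angle signs are derived so the composition flattens the detected plane
  (exactly for single-axis tilts, to first order for combined small tilts —
  residual < 0.2° at 5°, which is the tested bound).
* **Stitching** translates each leveled ROI by its frame's local track
  position and concatenates. Overlap from GPS jitter is kept, not
  deduplicated: the downstream raster takes per-cell maxima, for which
  duplicates are harmless.

All motions are rigid; point counts and pairwise distances are preserved to
1e−9, which the suite asserts.

## Segmentation

* **Vegetation.** ExG = 2g − r − b on sum-normalized RGB, threshold 0.15.
  Chromatic normalization makes the cut brightness-invariant; an all-zero
  color is defined as ExG 0.
* **Raster.** Half-open 0.05 m bins anchored at the cloud minimum, with the
  global maximum closed into the last bin so every point maps to exactly
  one cell; each cell stores its max height and remembers its point set.
* **Height cut.** Cells at or above the 30th percentile (linear
  interpolation) of the *non-empty* cells survive. "All pixels" is
  ambiguous when most of the grid is empty; using filled cells only keeps
  the threshold meaningful for sparse stands.
* **Components.** 8-connected labeling; area ≥ 15 cells to survive; the
  largest surviving component (ties → lowest label) is the main canopy. A
  component is canopy iff its centroid lies within the main component's
  bounding-box extent along the row axis (in cells) of the main centroid.
  The row-axis extent is used because between-plot weeds are displaced
  along the row; the across-row extent is available via configuration
  (`main_cc_axis`), as either reading of "bounding-box width" is
  defensible.
* **Scoring.** Accuracy/FPR/FNR in percent over vegetation cells; 0/0
  rates are 0. Category precedence: clean (accuracy ≥ 95) before
  under-removal (FPR ≥ 10) before over-removal (FNR ≥ 10), else other —
  the categories are reported as mutually exclusive.

## Traits

Heights and the 19-point cumulative height profile (5th–95th percentile,
linear interpolation) come straight from canopy z. Widths split the y
extent into 10 equal segments and measure max(x) − min(x) per non-empty
segment; empty segments are excluded from max/mean by default (a poorly
germinated plot would otherwise have its mean dragged to zero), with an
include-empty option. Projected area is the alpha-shape area of the X-Y
projection (Delaunay triangles with circumradius ≤ α, summed — Delaunay
simplices partition the hull, so the sum is the union area); α → ∞ gives
the convex hull. Volumes: 3D convex hull, and a 3D alpha shape
(tetrahedra with circumradius ≤ α) for the concave hull. α defaults to
0.10 m, twice the raster cell, large enough to bridge sampling gaps and
small enough to follow stand boundaries; no algorithm is canonical for a
"concave hull", and the alpha shape is the standard constructive choice.
Undefined traits (empty cloud; area below 3 points; volume below 4) are
NaN, never 0, so regressions drop them; degenerate-but-present geometry
(collinear projection, coplanar cloud) yields 0 with a warning.

A nadir sensor sees only the top surface: hull volumes systematically
underestimate whole-plant volume (no undersides), and the concave volume of
a surface shell is much smaller than the convex volume. Both still track
canopy size monotonically, which is what the growth and yield analyses use.

Growth rate per trait and period is the difference quotient between
consecutive observation dates (days after planting); the first period runs
from planting (trait 0 at day 0) to the first observation. Duplicate dates
are an error; NaN endpoints give NaN rates.

## Statistics

OLS through statsmodels with an intercept; adjusted R², RMSE on fitted
values, overall model F p-value, and significance tiers (<0.001, <0.01,
<0.05). Missing values are deleted listwise per regression. Rank-deficient
designs are an error that names the collinear columns. The nested F-test
uses the stored RSS and residual df of two fits on identical observations,
F = ((RSS_s − RSS_b)/df₁)/(RSS_b/df₂); its type-I error is calibrated to
0.05 (tested within [0.03, 0.07] over 2000 seeded null simulations).
Regressions pool all plots (no genotype terms); the long-format report has
one row per trait plus one for the height-profile model with the nested
test against the (max, mean) height model.

## Virtual field (synthetic data)

The generator emulates the target protocol: 3.05 m plots, 1.83 m alleys,
1.52 m row spacing, camera 2.4 m above ground at 1 m/s, one frame per
0.4 m (~2.5 Hz). Plants are half-ellipsoid domes, 15 per plot at 0.15 m
spacing starting 0.15 m into the plot (so the stand occupies 2.4 m),
heights 0.5–0.8 m and radii 0.25–0.35 m — overlapping into a continuous
canopy ridge, as a closed row-crop canopy presents to a nadir sensor.
Weed pressure is deliberately heavy, since weed removal is the subject
under test: 25 short in-row weeds per plot (0.08–0.28 m tall, 0.05–0.10 m
radius, scattered beside the row inside the enclosure) and one tall weed
(0.9–1.1 m) per alley. Under these conditions weeds hold roughly a third
of the vegetated cells, so the 30th-percentile height cut lands among weed
heights rather than inside the canopy's own height distribution — the
regime the percentile rule is designed for. Noise defaults: 5 mm Gaussian
depth noise applied before millimeter quantization, 2 cm GPS jitter;
ground tilt is configurable and defaults to level.

Rendering is exact per-pixel ray casting against the analytic surface
(height-field maximum over solids plus ground): the first crossing of the
pinhole ray is bracketed by a 2 cm march in depth and refined by 30
bisections, so a noise-free scene reconstructs to points on the generating
surfaces (≥ 99% within 5 mm end-to-end, verified). Per-pixel class maps
(ground/canopy/weed), closed-form per-plot traits (max height, footprint
union area via polygonized disks, per-solid volumes), and a footprint-based
cell labeler for scoring reconstructed clouds are emitted alongside.

What the virtual field does *not* model: leaf-level architecture and gaps,
radiometric/material effects on ToF depth (multipath, mixed pixels),
motion blur, GPS dropouts, and real weed morphology. Passing tests
demonstrate the pipeline's geometric and logical correctness under the
stated conditions, not field-ready accuracy on real imagery.

## Problem sizes and determinism

The test suite and acceptance script use a compact virtual camera (160×120,
f = 130 px — same geometry, fewer pixels than the field sensor) and
two-plot fields; sessions are ~20 frames. Hull/area recovery checks use
50k-point samples. Every random component (scene layout, noise, MLESAC,
simulations) is seeded; renders, reconstructions and trait tables are
byte-reproducible for a fixed seed and configuration.

## Known limitations

* The position rule cannot reject a tall alley weed whose centroid falls
  within the main canopy's row extent of the canopy centroid; with a full
  stand, the sliver of an alley weed that enters the plot ROI is therefore
  usually kept (a small FPR contribution, and an inflated max height when
  that weed is taller than the crop). This mirrors the rule as defined, not
  an implementation shortcut.
* The two-rotation leveling is exact only for single-axis ground tilt;
  combined tilts leave a second-order residual (≪ 0.2° at realistic tilt).
* One travel line is fitted per plot; a per-row fit would be preferable for
  very short plots with poor GPS, and the grouping step assumes rows run
  along the northing axis of the layout frame (or a pre-rotated layout).
* Hull volumes are top-surface volumes (see above), and projected area
  after segmentation excludes the canopy skirt removed by the height cut.
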