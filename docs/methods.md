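# Methods

This note documents the models, conventions and numerical choices behind
`icspectrum`, and what the synthetic validation does and does not establish.

## The measurement model

An en-face OCTA slab of the superficial plexus is treated as a 2D grayscale
raster with physical pitch `fov_mm / grid_px` (2.93 µm/px at the reference
1024 px over 3 mm).  Intercapillary spaces are the connected non-vessel
components inside the central 2-mm circle after adaptive binarization.  The
space containing the image center is the foveal avascular zone; if the
center pixel itself binarizes as vessel, the nearest space by Euclidean
distance is taken (this fallback triggers only on degenerate inputs).  The
FAZ is excluded from every per-eye summary.

### Binarization

Phansalkar thresholding classifies pixel *I* as vessel iff
`I > m·(1 + p·exp(−q·m) + k·(s/r − 1))` with local mean `m` and *population*
standard deviation `s` over a circular window.  Conventions:

* window radius 15 px at the 1024-px reference, scaled proportionally at
  other rasters (`default_run_config`); constants k = 0.25, r = 0.5, p = 2,
  q = 10 — the common reference parameterization for [0, 1]-normalized
  images.  None of these constants is dictated by the measurement itself, so
  all are config-exposed.
* border handling: windows are clipped at the image edge and statistics
  taken over the in-image part.  This makes interior output invariant to
  padding (asserted in tests).
* the local moments are computed as exact row-decomposed box sums of the
  disk window.  An FFT implementation was rejected: round-off produced
  slightly negative thresholds in exactly-zero background, which flips the
  strict `>` comparison for zero-intensity pixels.  Moments are additionally
  clamped to the valid range of [0, 1] statistics.
* thresholding runs on the full rectangular image first; the circular ROI is
  applied afterwards, so local statistics are undistorted at the circle rim.

The denoising step is a Gaussian blur whose "radius" parameter is the
standard deviation in pixels (σ = radius, kernel truncated at 3σ), the
convention of the common image-processing tools; DC gain is exactly 1.

### Morphometry

* **Area** = pixel count · pitch².
* **Perimeter** = Moore-traced outer boundary of pixel centers, summed with
  the classic chain-code weights (1 axial, √2 diagonal), **plus 4 px** to
  close the half-pixel outline the center chain cannot see.  With this
  convention an s × s px square measures exactly 4·s, a single pixel 4, and
  the isoperimetric bound `area ≤ perimeter²/4π · (1 + 5 %)` holds for all
  regions including 1–2 px ones (the raw chain code violates it there, and
  gives perimeter 0 for a single pixel).  For smooth contours the chain code
  overestimates length by ≈ 5 %; the validation tolerances absorb this known
  digital bias.  Interior holes (a space completely surrounding a vessel
  island) contribute pixel count but not perimeter; such configurations are
  vanishingly rare at capillary scale.
* **Feret diameters** are computed on the pixel-*corner* hull of the region
  boundary (so an s-px-wide region measures s, not s − 1): maximum = hull
  diameter, minimum = rotating-calipers width.  Collinear point sets return
  (0, L).
* Spaces use 4-connectivity by default (vessels implicitly 8-connected), so
  a one-pixel diagonal vessel line still separates spaces; 8-connectivity is
  available.  Regions touching the ROI rim are included and flagged; no
  minimum-size filter is applied by default.  Both choices are config
  switches (`include_edge_regions`, `min_area_px`).

### Per-eye spectrum and cohort statistics

Per eye (FAZ excluded): total count; arithmetic means of area, perimeter,
min/max diameter; counts of spaces with area strictly greater than 0.01–0.05
mm²; count of spaces with area/perimeter ratio strictly greater than
0.025 (for a disk of radius ρ the ratio tends to ρ/2, so the threshold flags
smooth spaces wider than ~0.1 mm).  All thresholds use strict `>`.
Means are undefined (NaN) for an eye with no spaces.

Cohort layer: Kruskal–Wallis omnibus (tie-corrected) with pairwise
two-sided Mann–Whitney tests, Bonferroni factor = number of pairs actually
compared within one parameter's family; Spearman correlation as Pearson on
midranks with the t-approximate p; Fisher's exact two-sided p by
minimum-likelihood summation over the hypergeometric distribution with
fixed margins, computed in exact integer arithmetic (the "doubling"
convention differs and is not used); odds ratio reported as ad/bc.  ROC
curves are empirical threshold sweeps with trapezoidal AUC (ties credited
0.5, hence AUC ≡ normalized Mann–Whitney U); the AUC standard error uses the
Hanley–McNeil distribution-free formula and a normal 95 % CI clipped to
[0, 1].  Orientation is declared per parameter: the total count *decreases*
with disease and is negated; size/shape parameters increase.  Grade
groupings: diabetic vs nondiabetic; DR vs no apparent retinopathy;
referable DR (moderate NPDR or worse) vs milder; severe NPDR + PDR vs
milder diabetic grades; PDR vs NPDR.

## The synthetic scene model

The generator emulates the superficial plexus as a planar graph:

* blue-noise node sample (Bridson Poisson-disc, spacing √(0.68/density))
  joined by Delaunay edges — lobular, roughly honeycomb spaces like a real
  capillary mesh.  Default `seed_point_density` = 80 nodes/mm² puts ≈ 500
  spaces in the 2-mm circle of a healthy eye, the right order of magnitude
  for the macula.
* a protected vessel ring of radius `faz_radius_mm` (default 0.30 mm)
  guarantees a center-containing face; convex-hull boundary edges act as
  protected trunk vessels with 3× stroke width.
* capillary strokes are hard (no anti-aliasing) 12 µm lines: Bresenham
  pixels dilated by a discrete disk.  Vessel intensity 1, background 0,
  additive Gaussian noise (σ = 0.05 default) clipped to [0, 1].
* **permanent dropout**: each non-protected edge removed with probability
  `dropout_rate` for all frames — merges adjacent spaces into larger
  nonperfusion areas.  **Transient loss**: each surviving non-protected edge
  independently blanked per frame with probability `transient_rate`
  (default 0.05; there is no quantitative literature value — it is a free
  parameter, not an estimate).  Protected edges are exempt from both, so the
  FAZ ring and trunks persist.
* ground truth is exact: the faces of the alive planar line arrangement as
  shapely polygons (areas/perimeters analytic), cross-checked against the
  Euler-formula face count E − V + C.

What the model does **not** emulate: OCT speckle statistics (noise is i.i.d.
Gaussian, not multiplicative speckle), projection artifacts, vessel-caliber
heterogeneity beyond the trunk/capillary split, hemodynamics, the 3D
structure of the deep plexus, and inter-eye FAZ size variability.  Passing
the synthetic validation therefore demonstrates correctness of the
measurement chain, not clinical performance on device images.

## Validation conventions

Comparing pixel detections against polygon ground truth needs a geometric
bridge:

* a rasterized stroke of dilation radius ρ px covers
  `(2ρ+1)·max(|cos θ|, |sin θ|)` px² per pixel of length at orientation θ
  (verified against the rasterizer at 19 angles to < 0.5 %).  The *expected
  space pockets* are each face minus its nearby strokes buffered at this
  orientation-dependent half-width (`expected_space_pieces`).
* stroke overlap at acute junctions pinches off pixel pockets far below
  capillary scale; these have no polygonal counterpart.  Validation applies
  a debris floor of one stroke-width square, `(2ρ+1)²` px (≈ 25 px ≈
  2 × 10⁻⁴ mm² at 1024 px), on both the detected and predicted side.
* recovery runs on noise-free scenes disable the Gaussian blur (there is no
  speckle to suppress) — with it, the threshold halo widens strokes by about
  one pixel per side, which is the documented accuracy limit of the
  binarization (vessel recall ≥ 0.997 at any blur; dice 1.0 unblurred,
  ≈ 0.94 at σ = 1, ≈ 0.87 at σ = 2 on 5-px strokes).

Under these conventions a clean 1024-px eye yields space-count agreement
within ~3 % and per-face area agreement within ~4 % for faces ≥ 0.005 mm²;
a five-level dropout sweep (0–0.4, 20 eyes per level, 512-px raster for
runtime) gives Spearman |ρ| ≈ 0.95–0.98 between dropout and the spectrum
parameters, and the total count separates 30 %-dropout eyes from healthy
ones with AUC ≈ 1.  These are the quantities `scripts/acceptance.py`
recomputes.

## Problem sizes and determinism

Tests and the acceptance script use 384–512 px rasters for cohort-scale
simulation and the full 1024 px raster for single-eye recovery — the
spectrum metrics are expressed in mm/mm² and are resolution-consistent once
the blur radius and threshold window scale with pitch.  All randomness
flows from explicit integer seeds (`SceneConfig.rng_seed`, spawned
per-eye via `numpy.random.SeedSequence`); there is no global random state,
and identical configs and seeds reproduce outputs bit-for-bit.

## Known limitations

* The chain-code perimeter, like the particle analyzers it mirrors, carries
  a systematic ≈ +5 % bias on smooth contours; area/perimeter ratios are
  correspondingly ≈ 5 % low.  The estimator is isolated behind
  `chain_code_perimeter_px` and could be swapped for a Crofton-type
  estimator without touching the rest of the chain.
* Edge-touching spaces include the ROI rim in their perimeter; whether
  clinical analyses exclude such particles is generally unreported, so
  inclusion (flagged) is the default.
* Frames are assumed co-registered; only an optional integer-shift
  registration (`register_shift`) is provided.
* Repeat-frame averaging uses the arithmetic mean; no motion or
  signal-strength weighting.
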