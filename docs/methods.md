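# Methods

This note records the models implemented in `leafmsi`, the parameter
choices that matter, what the scene simulator does and does not emulate,
and the numerical decisions taken where the design was genuinely open.

## Imaging model and calibration

The device being emulated captures four monochrome transmittance images of
a pressed leaf (capture order NIR 880, red 660, green 560, blue 405 nm)
against a bright diffuse background, together with a white reference (no
leaf, LEDs on) and a dark reference (LEDs off). Flat-field calibration is

    I_cal = (I_raw − I_dark) / (I_white − I_dark),

applied per pixel and band. Any smooth illumination field shared by the
raw and white frames cancels exactly; the test suite verifies the three
identities raw=dark → 0, raw=white → 1, raw=dark+t·(white−dark) → t to
1 × 10⁻⁶ under a strong synthetic vignette. Pixels where white = dark are
flagged invalid (value 0) rather than propagating infinities, and output
is clipped to [−0.05, 1.5]: transmittance can slightly exceed 1 near
reference noise, but unbounded ratios would break NDVI downstream.

Spatial calibration consumes an externally estimated camera model: a 3 × 3
intrinsic matrix, Brown–Conrady coefficients (k1, k2, p1, p2, k3), and a
fixed mm/px scale derived once from the platform distance (the chamber
geometry is rigid, so no per-image scale estimation is attempted).
Undistortion remaps each ideal pixel through the forward distortion model
with bilinear sampling (nearest for masks, which must stay binary); zero
coefficients give the identity exactly. A `distort_image` helper inverts
the model by fixed-point iteration for simulation and round-trip tests
(interior PSNR > 40 dB). Estimating intrinsics from checkerboards is out
of scope. The processing order is calibrate → segment → undistort →
rotate; with the rigid chamber the distortion is small, so applying it
after segmentation (as the device flow implies) costs nothing measurable.

## Segmentation and petiole removal

NDVI = (NIR − red)/(NIR + red) per pixel; denominators under 10⁻⁹ are
invalid. Plant tissue transmits NIR strongly and red weakly, so lamina
NDVI is high (~0.7) while the white diffuser background stays near 0; the
threshold t = 0.2 separates them, with pixels at exactly t included
(`≥ t`). The largest 8-connected component is kept (noise speckle can
cross the threshold), and holes under `min_component_px` (64) are filled.

Leaf orientation θ ∈ (−90°, 90°] comes from the principal axis of the
mask's second-order central moments (counter-clockwise positive, y up).
Moments were preferred over a least-squares contour ellipse because they
are robust to ragged contours and testable against a closed-form oracle;
near-circular masks (anisotropy below 10⁻³ of the trace) return 0 with a
degenerate flag. Rotation to horizontal resamples intensity bands
bilinearly and the mask with nearest-neighbour on an expanded canvas; the
leaf pixel count changes by < 2%.

The petiole lies along the major axis on the right after rotation. Its
removal scans the per-column width profile rightward from the global
maximum and cuts at the first column whose width drops below `t_petiole`
(50 px); that column and everything right of it is zeroed. A blade that
itself tapers below 50 px right of its widest column is clipped there —
this is inherent to the width rule and the cut column is recorded so
callers can flag it. If no in-leaf column qualifies the mask is returned
unchanged. The rule is monotone: a larger threshold never retains more
pixels.

## Morphometrics

Area is the shoelace area of the sub-pixel marching-squares contour
(−0.03% on a 200-px-radius disk). Perimeter uses the same contour after a
circular moving-average of its vertices (window 5): the raw contour
zigzags at pixel scale and overestimates smooth perimeters by ~5.5%,
which would bias roundness of a disk to 0.90; smoothing brings disk,
square and ellipse perimeters within 0.8% while blunting corners by only
~0.1%. Axes are those of the moments-equivalent ellipse of the filled
region, consistent with the orientation fit. Roundness R = 4πA/P² is
scale-invariant by construction. On rasterised fixtures with minor axis
over 300 px the suite requires: disk roundness 1.00 ± 0.03, square
π/4 ± 0.03, ellipse axes within 2%, areas within 1.5%.

The NDVI preview for app transfer is exactly 192 × 120 (width × height),
produced by exact area averaging: cell sums are read off a padded integral
image evaluated at fractional coordinates (the integral of a
piecewise-constant image is piecewise bilinear, so order-1 interpolation
is exact). The global mean is preserved to machine precision.

## Ring sectioning

The leaf outline is scaled by factors 0.9 … 0.3 toward a scaling center
placed on the midrib at two-thirds of the major-axis extent from the tip
(the midrib is approximated by the major-axis chord; whether "two thirds
of the major vein" follows the vein curve is unknowable from a straight
midrib, so the chord is used). The tip is on the left after petiole
removal (flag `tip_side` if not). Section k is the set of mask pixels
between successive scaled contours, assigned by successive even-odd
rasterisation with innermost-wins, which guarantees every mask pixel gets
exactly one of the 8 labels even for concave or self-intersecting scaled
outlines. Contours longer than ~150 vertices are decimated before
rasterisation (area error ~0.1%; keeps sectioning well under a
second per leaf). Empty inner sections (tiny leaves) are reported missing
(NaN), not zero, to avoid biasing downstream comparisons.

## Venation

Veins transmit relatively less NIR, so they are dark in NDVI. Extraction:
Gaussian smoothing with a 5 × 5 kernel (σ from the usual 0.3·((k−1)/2−1)+0.8
rule), an adaptive threshold against the local mean over a 51 × 51 block,
restriction to the leaf, and removal of 8-connected components strictly
smaller than 71 px. Two local choices matter:

- the local mean is computed over leaf pixels only (normalised box
  filter), so the zero background cannot depress the threshold near the
  margin and spuriously mark the whole leaf edge;
- the threshold is `local mean − offset` with offset 0.08 NDVI units.
  With a zero offset every faintly smoothed halo pixel around a vein falls
  below the local mean, bounding precision by roughly w/(w+4) for veins of
  width w (~0.55 at width 5) regardless of contrast. 0.08 is about a
  quarter of the typical lamina–vein NDVI contrast (~0.3) and far above
  the per-pixel NDVI noise floor; with it, recall and precision against
  simulator ground truth are ≥ 0.95 on lattice and organic scenes alike.
  Veins fainter than the offset are invisible by design — raise or lower
  it for other contrasts.

The vein mask is thinned to a one-pixel skeleton. Pixels with ≠ 2
neighbours are node pixels; adjacent node pixels within a 2-px radius are
merged (thinning produces small clusters at Y-junctions). Edges are traced
between node clusters; pure loops with no node get an anchor node and a
self-loop so component and cycle counts stay exact. Edge length is the
Euclidean length of the traced path subsampled every 5 pixels (per-pixel
1/√2 chain weighting overestimates oblique strokes by up to ~8%; the
subsampled polyline is exact for straight and 45° strokes and keeps a
lattice's total length within 3% under rotation). Edge width is
2·(mean distance transform along the centerline) − 1, the −1 correcting
the half-pixel offset so a 9-px stroke reads 9. Degree-2 bend nodes are
contracted. Features: junction count (degree ≥ 3), endpoint count
(degree 1), cycles by the Euler identity E − V + components (exact by
construction), total length, vein-mask area, convex-hull area, and average
edge length and width.

## Regression

`linear_fit` is ordinary least squares of a reference value on one
predictor (e.g. SPAD on mean NDVI), scored in-sample.
`mlr_interaction_loocv` regresses on the four band means plus all six
pairwise products (11 columns with intercept; "with interaction" is read
as all pairwise products — the enumeration is not specified anywhere, so
this choice is prominent and deliberate). n must exceed 11. Leave-one-out
predictions use the exact hat-matrix identity e_i/(1 − h_ii), verified in
the tests against literal refitting; R²_cv = 1 − SSE_cv/SST (the
squared-correlation alternative is rejected because it hides bias), and
RMSE_cv ≥ in-sample RMSE always. Rank-deficient designs are rejected with
the collinear columns named. The headline accuracies reported for the
physical device depend on its greenhouse dataset, which is not deposited;
the suite therefore tests recovery on synthetic generating models
(noiseless LOOCV R² ≥ 0.999; a true interaction coefficient recovered
within 10% at n = 40, σ = 0.05).

## Scene simulator

The simulator stands in for the physical capture. Defaults model the
chamber at desk scale: a 620 × 400 px field at 0.2 mm/px (the 124 × 80 mm
chamber), a superellipse leaflet |u/a|ᵉ + |v/b|ᵉ ≤ 1 with a = 180 px,
b = 100 px, e = 2 (e > 2 sharpens the tip; e = 2 gives closed-form area
πab and a Γ-function formula in general), a 90 × 14 px petiole at the base
end of the major axis, and a vein network (midrib plus 6 primary pairs
with two levels of side-branching, 5 px wide) drawn in the leaf frame and
clipped to the blade. Per-band transmittances: lamina NIR 0.80 / red 0.10
(NDVI ≈ 0.78), veins 0.75/0.28 (≈ 0.46), background 0.97/0.95 (≈ 0.01) —
plant tissue far above and the diffuser far below the 0.2 threshold. The
edge-to-center NDVI gradient (default +0.10) is realised exactly by
deriving the red transmittance per pixel from a target NDVI field built on
the normalised distance-to-edge; NIR stays fixed. Counts follow
dark + illum · τ · (plateau − dark) + noise with a radial vignette
(strength 0.30), dark level 100, plateau 3000 and Gaussian noise
(σ = 15 counts ≈ 0.5% of range; sweeps go to 2%). Raw counts stay float
by default so calibration identities hold to 10⁻⁶; a `quantize` flag
rounds to uint16 for IO realism (the physical ADC is 12-bit, but the
stored bit depth is a container choice). One seed spawns independent
per-band streams, so outputs are bit-identical for identical parameters.

Ground truth carries the lamina/petiole/vein masks, the construction-time
vein graph, the applied orientation, and closed-form morphology
(superellipse area, numerically integrated perimeter, extent axes).
`generate_vein_lattice` supplies the analytic topology fixture: the grid
graph on rows × cols nodes drawn as strokes, with corner (degree-2) nodes
contracted — so a 3 × 3 lattice has 5 junctions, 0 endpoints and
(rows−1)(cols−1) = 4 cycles, and a 1 × 2 lattice is a single stroke with
two endpoints.

What the simulator does **not** emulate: radiative transfer or chlorophyll
biochemistry (transmittances are set, not derived), specular effects,
leaf curvature or pressing artefacts, disease lesions, multi-leaflet
scenes, and realistic vein-order geometry (the synthetic network covers
~25–30% of the blade, denser at the midrib than real soybean venation, so
whole-section NDVI means on fully veined scenes mix the gradient with vein
placement; gradient-recovery checks therefore run on vein-free scenes that
isolate the mechanism). Passing tests demonstrate the correctness of the
measurement chain on known geometry, not the biological fidelity of any
feature distribution.

## Problem sizes and determinism

All simulations run at the 620 × 400 px desk scale described above; the
segmentation acceptance sweep uses 20 seeded scenes with orientations
within ±18° (a full-size leaf physically cannot tilt further inside the
chamber) and noise up to 2% of range. Every random draw in the package,
tests and acceptance script flows from an explicit seed; the same seed
reproduces byte-identical scenes and feature tables.

## Known limitations

- The petiole rule can clip a blade tip that tapers below `t_petiole`
  right of the widest column (documented above; `cut_col` exposes it).
- Width thresholds are in pixels, not mm, matching the device's
  dimensionless constant; change `t_petiole` when the scale changes.
- The venation estimators (subsampled length, EDT width) are validated
  against analytic fixtures only; no manually labelled vein ground truth
  exists here.
- `fit_orientation` is ambiguous for near-circular leaves (flagged) and
  the tip-side convention assumes the petiole was on the right.
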