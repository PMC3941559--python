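# Methods

## The measurement model

`respivol` implements a marker-based photogrammetric model of
thoracoabdominal kinematics for a supine subject performing a forced
vital capacity maneuver. Five circular adhesive markers of known diameter
(13 mm) are placed over the manubrium sterni (MEd), the xiphoid process
(AXd), the inferior angle of the 10th rib (ACd), the umbilicus (COd) and
the right anterior superior iliac spine (EId). A lateral camera records
the maneuver; from the clip, two frames are taken at the extremes of
maximal expiration and maximal inspiration.

Processing one frame proceeds in three stages:

1. **Detection** (`respivol.imaging`). Markers are dark circles on a
   light background. The detector thresholds the raster (Otsu), labels
   connected components, and keeps blobs whose circularity
   4πA/P² ≥ 0.6. Sub-pixel centers and diameters are then measured on a
   *coverage map*: inside a padded box around each blob, the local
   background level is estimated from the above-threshold pixels and each
   pixel's darkness fraction is treated as fractional disk coverage. The
   center is the coverage-weighted centroid and the diameter the
   equivalent-area circle diameter of the total coverage. On anti-aliased
   circles this recovers centers and diameters to well under 0.1 px; with
   additive Gaussian noise of SD 10 gray levels the diameter error stays
   below about 0.3 px. Candidates are ranked by circularity × area and
   ties broken by smaller x, so detection is deterministic.

2. **Calibration**. The metric scale is `mm_per_px = 13 / median(diameters)`.
   The median makes the scale robust to one badly segmented marker. When a
   subject contributes both phases, the ten diameters of both frames are
   pooled into a single per-subject scale: the camera does not move
   between the two extreme frames of one maneuver, and because the
   mobility is a *difference* of two large volumes, even a 0.1% scale
   mismatch between independently calibrated frames would be amplified
   roughly by the ratio of total volume to mobility (an order of
   magnitude) in the mobility estimate.

3. **Volumetry** (`respivol.volumetry`). The physical frame is sagittal:
   x runs craniocaudally (cm, origin under MEd), y is height above the
   support surface (cm). Adjacent landmarks delimit four compartments —
   upper thorax UT (MEd–AXd), lower thorax LT (AXd–ACd), upper abdomen UA
   (ACd–COd), lower abdomen LA (COd–EId). Each compartment is the
   trapezoid bounded above by the straight segment joining its two
   landmarks, below by the bed line y = 0, and laterally by vertical feet
   dropped from the landmarks. Areas are shoelace areas; volumes are the
   areas extruded through the caliper-measured thorax length:
   `V [l] = A [cm²] × L [cm] / 1000`. Totals are additive by construction
   (TT = UT+LT, TA = UA+LA, thoracoabdominal = TT+TA). The **total
   volumetric mobility** is the inspiration minus expiration
   thoracoabdominal volume; it is the kinematic predictor of the
   spirometry equations.

Two design points of the volumetry were genuinely open and were fixed as
follows. The closing boundary of the profile is the support surface
(bed line): it is the only physically motivated reference for a supine
subject, and choosing it makes volumes strictly monotone in marker
height. The extrusion depth is one uniform thorax length for all four
compartments, since a single caliper measurement is the only depth
available; the resulting "volumes" are therefore *index* quantities
(tens of litres for the whole trunk prism) rather than anatomical gas
volumes, and only their differences and correlations carry meaning.

## Prediction and screening

Two published linear equations map (height m, thorax cm, mobility l) to
spirometric outcomes in litres:

    FVC = −8.572 + 5.108·height + 0.138·thorax + 0.120·mobility
    DI  = −6.373 + 3.751·height + 0.122·thorax + 0.163·mobility

They ship as read-only JSON fixtures (`respivol/models/`). The reported
fit metadata is stored as printed; note that for the DI model the printed
R (0.881) and R² (0.815) are not mutually consistent (0.881² = 0.776), so
the R² = R² consistency invariant is enforced only on freshly fitted
models. The "standard deviation" accompanying each published fit (0.353 l
for FVC, 0.451 l for DI) is interpreted as the regression standard error
of the estimate (SEE): it accompanies an R² of a fitted model, where a
plain outcome SD would be redundant with the cohort table.

`fit_model` refits the same three-predictor form by ordinary least
squares (statsmodels), reporting R as the multiple correlation of fitted
vs observed values and SEE = sqrt(RSS/(n−4)). Rank-deficient designs
raise an error naming the collinear column; a constant outcome returns
zero slopes with NaN R and a warning.

Screening applies the Tiffeneau rule: subjects with FEV1/FVC strictly
below 0.80 (a ratio, computed before any rounding) are excluded as
showing obstruction; an optional user-supplied FVC lower limit flags
possible restriction. No default FVC limit exists because it must come
from a reference equation chosen for the population at hand.

## Agreement statistics

Pearson correlations use the sample estimator and refuse constant
vectors. Bland-Altman agreement takes differences method1 − method2,
bias = mean difference, limits of agreement = bias ± 1.96·SD with the
sample (n−1) SD — 1.96 is a fixed constant, not a configurable quantile.
The companion bias test is a two-sided one-sample t-test at α = 0.05
(degenerate zero-variance differences report p = 1 for zero bias, else
p = 0). Cohort summaries report mean/SD/min/max per variable; a
single-subject cohort reports SD = 0.

## The synthetic cohort generator

No recorded video or subject table is distributable, so
`respivol.synthetic` generates the full study from published cohort
statistics; every random draw flows from one explicit integer seed.

**Anthropometrics.** Age, body mass, height and thorax length are
rejection-sampled truncated normals with the published mean/SD as parent
parameters and the published min/max as hard bounds. Because those
bounds are sample extremes of a 40-subject cohort, truncating at them
shaves roughly 15% off every SD and shifts means slightly toward the
interval centers (mean height ≈ 1.675 vs 1.66); moment-matching the
truncated distribution to the printed mean/SD instead is not possible —
the printed height and mass SDs sit at the uniform-distribution limit of
their intervals.

**Correlation structure.** Body size variables (height, mass, thorax,
mobility, resting trunk volume) load with weight 0.9 on a shared latent
growth factor. Independent draws cannot reproduce the published joint
statistics; the loading and the mobility SD (1.0 l, not published) were
solved jointly from two published quantities — the cohort FVC SD
(0.91 l) and the mobility–FVC correlation (0.812) — and the resulting
±3 SD mobility range (0.75–6.75 l) brackets the mobility implied by the
published per-phase extreme totals (2.05–6.79 l).

**Inverse kinematics.** `make_kinematics` constructs marker positions
realizing a prescribed mobility exactly. Expiration compartment volumes
are proportioned as the published expiration means and scaled to a
sampled resting total; marker x-spacings are solved so a jittered supine
profile template (chest plateau dropping to the abdomen) attains those
areas over a trunk length of 27% of stature — this parameterization is
feasible and positive by construction, unlike solving heights at fixed
spacings, which goes negative for abdomen/thorax area ratios like the
published ones. The inspiration frame moves markers vertically only
(the anterior wall of a supine subject displaces essentially
perpendicular to the bed) by the minimum-norm height correction whose
area increments distribute the target mobility over compartments in the
published recruitment proportions (UT:LT:UA:LA ≈ 1.09:1.75:0.60:0.30).
Forward volumetry on the constructed coordinates reproduces the target
mobility to better than 1e-9 l, which the test suite verifies over random
subjects. Configurations that would push a marker below the bed or above
a plausible supine profile (60 cm) raise an invalid-configuration error.

**Rendering.** Frames are 8-bit grayscale rasters with five filled
circles of diameter 13 mm / mm_per_px on a light (235) background, drawn
with analytic per-pixel coverage anti-aliasing so ground-truth centers
and diameters are recoverable to sub-pixel accuracy; optional additive
Gaussian noise (SD in gray levels) is applied after drawing. The
ground-truth scale is drawn uniformly from 0.6–1.0 mm/px, the range a
consumer camcorder two meters from a subject would produce.

**Simulated spirometry.** Measured FVC and DI are the published equation
predictions plus Gaussian residuals with the published SEEs (0.353 and
0.451 l); FEV1 follows from a Tiffeneau ratio drawn from the retained
range (truncated normal 0.832 ± 0.04 on [0.80, 0.95]; 0.832 is the ratio
of the published FEV1 and FVC means) and PEF is an independent truncated
normal with the published moments.

**What the generator does not emulate.** Real torso texture, lens and
perspective distortion, motion blur, marker occlusion or deformation,
sex-specific breathing patterns, and within-subject trial-to-trial
variability of marker placement (unquantified in the source study; pixel
noise is configurable but not calibrated). Passing end-to-end tests
therefore demonstrates correctness of the geometry, detection and
statistics chain — not field robustness to real video.

## Regression-recovery simulations

For simulations of the regression *fit* (coefficient recovery, refit
quality), predictors are drawn by `sample_regression_cohort`: correlated
normals with the published means/SDs and the shared size factor but
WITHOUT range truncation. The published model fits were obtained under
the full cohort dispersion; clipping at the printed extremes would
understate the predictor spread and with it the achievable fit quality.
Under these conditions, 500 replicates of n = 40 with residual SD
0.353 l recover unbiased coefficients and a mean refit R² of ≈ 0.86.

## Numerical choices and problem sizes

- Internal computation is double precision; volumes are rounded to two
  decimals only at reporting, correlations to three.
- Detection tie-breaks: equal scores ordered by smaller center x.
- Landmark assignment refuses markers closer than 2 px along the body
  axis (ambiguous craniocaudal ordering).
- Polygon areas validate simplicity with an O(n²) proper-intersection
  test before the shoelace formula; degenerate zero-height profiles
  return zero area rather than an error.
- Test problem sizes: 2000 subjects for population statistics, 100
  random conditions for the forward/inverse round trip, 500 replicates
  of n = 40 for the coefficient-recovery simulation, 50 random profiles
  against a 0.02 cm rasterization oracle, and 20 subjects through the
  full render→detect→calibrate→measure chain.

## Known limitations

- The extruded volumes are prism indices, not gas volumes; absolute
  values depend on the bed-line closure convention and the single-depth
  extrusion and should only be compared within the same convention.
- Five landmarks constrain a piecewise-linear profile; no spline or
  higher-order surface is attempted.
- The detector assumes markers are the only dark circular blobs of their
  size class in the frame; it does not segment the body contour.
- The camera viewpoint is assumed lateral with the body axis along image
  x; frame selection from a full video clip is out of scope.
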