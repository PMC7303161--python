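# Methods

## What the package computes

`rvkinergy` quantifies right-ventricular (RV) diastolic function from
4D-flow cardiac MR through two complementary channels:

1. **Intracavity blood-flow kinetic energy (KE).** The endocardial
   segmentation of the short-axis cine stack is turned into a time-resolved
   RV volume; every flow voxel inside it contributes

       KE_voxel = 1/2 · ρ_blood · V_voxel · v_voxel²

   with ρ_blood = 1.06 g/cm³, V_voxel the voxel volume in cm³ and v_voxel
   the velocity magnitude in cm/s. This product is in erg (the cgs energy
   unit); 1 erg = 0.1 µJ. The cgs→µJ conversion is the most error-prone
   step of the whole chain and is centralised in a single constant
   (`ke_mapping.ERG_TO_UJ`). Per-phase totals are divided by the
   cine-derived end-diastolic volume (KEi_EDV, µJ/ml) and the curve is
   condensed into six parameters: global (cycle mean), systolic mean,
   diastolic mean, cycle minimum, the early-diastolic (E) and atrial (A)
   filling peaks, and the E/A ratio — the diastolic index of interest.

2. **Tricuspid through-plane flow by retrospective valve tracking.** A
   measurement plane follows the tricuspid annulus (landmarks from the 4-
   and 2-chamber views), velocities are reformatted onto it, projected
   onto the inflow normal, background-corrected with the mean velocity
   sampled in the adjacent myocardium, and integrated over the valve
   aperture: flow-rate curve, tricuspid stroke volume (TV SV), and the
   diastolic E/A peak velocities.

Cohort-level statistics (sex descriptives with t-tests, Spearman age
correlations, univariate + forward-conditional multivariate regression,
Kruskal–Wallis/Dunn age-group comparisons with significance letters, Lin's
concordance and coefficient-of-variability reproducibility metrics)
operate on a per-subject metric table.

## Geometry pipeline

* **Contour propagation.** Manual contours exist at keyframe phases
  (0-based {0, 5, 11, 17, 23} of 30). Each keyframe polygon is resampled
  to 64 rays at uniform angles from its area centroid; per-ray radius and
  centroid are interpolated linearly in phase between flanking keyframes,
  cyclically across the R-R wrap. Keyframe phases return the original
  polygons untouched. A slice present in only one flanking keyframe is
  ramped to zero *area* (radius × √weight) and logged. Linear radius
  interpolation between sparse keyframes undersamples fast volume
  transients around end-systole; this reproduces the information loss of
  keyframe-based clinical workflows and is quantified in the tests.
* **Cylindrical mesh.** Axial levels are midpoints of equal slabs spanning
  the disc extent (default 3 levels/slice); the radius at a level/angle is
  interpolated linearly in z between the flanking slice contours' ray
  radii (constant extrapolation beyond the outermost slice centers);
  enclosed volume is Σ ½ r² Δθ Δz (128 angles by default; the cylinder
  benchmark is accurate to 0.05 % already at 64).
* **Voxel masks.** A voxel belongs to the RV when its center lies in a
  level slab and within the angle-interpolated radius; centers exactly on
  the surface are inside (closed-boundary rule). Slab lookup uses index
  arithmetic, not floating-point interval tests, so commensurate grids do
  not drop layers.
* **Volumetrics.** Disc summation of contour areas; EDV = max, ESV = min
  with ties broken to the earliest phase; EF = 100·(EDV−ESV)/EDV; indexed
  variants divide by BSA. TAPSE projects the lateral annulus displacement
  onto the apex-ward long axis; right atrial area is a shoelace area
  reported in cm² (clinical tables sometimes label this column "mm"; the
  unit here is cm², with the BSA-indexed twin in cm²/m²).

## Velocity corrections

* **Unwrapping.** Components jumping by more than 1.0·VENC against the
  median of their 3×3×3 spatial neighbourhood across adjacent phases are
  shifted by the nearest multiple of 2·VENC; sweeps repeat to a fixed
  point so wrapped regions erode from the rim inwards. Only single wraps
  are corrected; larger excursions are counted and flagged. Corrections
  are exact multiples of 2·VENC, so structurally correct output equals
  truth bit-for-bit — the round-trip test exploits this.
* **Local phase correction (LPC).** Static tissue is detected as voxels
  with temporal speed SD < 2 cm/s and magnitude ≥ 20 % of the volume
  median (thresholds are conventions; the concept, not the numbers, is
  standard). Per slice and component, the offset surface is the
  magnitude-weighted moving average (24 mm window ≈ 8 voxels at 3 mm) of
  the temporal-mean velocity over static voxels, subtracted from all
  phases; regions beyond the window's reach receive the slice-wide
  weighted mean. A weighted mean rather than a polynomial fit matches the
  "spatial low-pass filter" character of the correction. Residuals are
  assessed over the signal-bearing region: air at the FOV margin carries
  no phase information for any offset estimator.
* **Rigid realignment.** A user-supplied rotation (about the volume
  center) + translation; the grid is resampled trilinearly and velocity
  vectors are rotated by the same matrix. Estimating the transform (image
  registration) is out of scope.

## The flow phantom

The phantom is a stack of short-axis discs (10 slices, apex tapered by
30 %) whose regular-polygon contours are inflated so the *shoelace* disc
summation reproduces the programmed volume exactly — the contour stack is
its own volumetric ground truth. Cavity volume traces EDV → ESV → EDV
(half-cosine emptying; two-stage smooth refilling with 60 % of the volume
in the first 55 % of diastole), so dV/dt exhibits E and A waves. Inside
the cavity the velocity is long-axis aligned with a spatially uniform
per-phase magnitude following three sin² bumps (systolic, E, A); uniform
speed makes the total KE exactly 0.05 · 1.06 · V(t) · v(t)² µJ in closed
form. A parabolic (Poiseuille-like, peak = 2× mean) profile is available
for realism and for localised-aliasing experiments; its truth comes from
the voxel oracle instead of the closed form. Since no intracavity velocity
profile is reported for this kind of acquisition, the uniform profile is an
acknowledged idealisation.

Details that make the oracle checks meaningful rather than lucky:

* the cavity height is an integer number of voxel layers with its axial
  faces midway between voxel-center planes, so voxel membership carries no
  axial quantisation bias and the ≤1 % per-phase KE agreement measures
  genuine in-plane discretisation;
* the in-plane center is offset off the grid symmetry axes (0.4/0.3
  voxels) so per-slice membership errors decorrelate across the tapered
  slices.

**Mass conservation.** With `conserve_mass` (default on) the diastolic
speed program is rescaled by one factor so the inflow through the valve
plane integrates exactly to the cine stroke volume — the phantom then
behaves as an incompressible filling chamber and TV SV ≡ EDV−ESV is a
cross-modality conservation check. The E/A speed ratio is unchanged by the
rescaling. `calibrate_ea_ratio` solves for v_a in closed form so the truth
KEi_EDV E/A ratio hits a requested value (E and A bumps have disjoint
support, so the ratio is (v_e/v_a)²·V(t_E)/V(t_A)).

Defaults emulate the target acquisition: 30 phases at 40 ms, 3 mm
isotropic voxels, VENC 150 cm/s, EDV/ESV 150/60 ml (EF 60 %), end-systole
at phase 10, velocity noise SD 1.5 cm/s (a low-noise in-vivo-like floor;
set 0 for oracle checks). The annular track places four landmarks on the
third-from-base slice contour; the generated aperture polygon is that
contour dilated by 1.5 voxels so the trilinearly smoothed jet edge is
integrated in full (interpolation conserves the flux integral, but only if
the aperture captures the smoothed tail).

What the phantom does **not** emulate: chamber shape irregularity,
trabeculation, vortical/secondary flow, heart-rate variability between
cine and flow acquisitions, respiratory motion, eddy-current spatial
structure beyond constant/linear offsets, or partial-volume basal discs.
Passing phantom tests therefore validates the *computational chain*
(geometry, unit chain, integration, statistics), not robustness to
in-vivo segmentation or flow complexity.

## The synthetic cohort

Per-subject metrics are drawn with a Gaussian copula. The age latent is
z0 = w(u1+u2) + √(1−2w²)·e0 with w = 0.68. A metric programmed with rank
correlation ρ loads either on z0 directly or — when tagged as an
independent predictor — on u1 or u2 alone, scaled so its latent
correlation with z0 is 2·sin(πρ/6), which makes the *Spearman* correlation
of the Gaussian pair exactly ρ. Ages map uniformly onto 20–80 years;
metrics map onto zero-truncated Gaussians with the calibrated mean/SD
(reference values for a healthy adult cohort); both maps are strictly
monotone, so programmed rank correlations survive unchanged. By default
the KEi_EDV E/A ratio (ρ = −0.531) and TV SV (ρ = −0.434) are the two
independent predictors; peak-A KE (ρ = +0.42) and the rest load on the
common factor. Marginals are mean±SD summaries only — joint structure
beyond the programmed correlations is not modelled.

## Statistics conventions

* Spearman with mid-ranks and the t approximation for p.
* Independent t-test with pooled variance (Welch available via flag).
* Kruskal–Wallis tie-corrected; Dunn z on mean ranks with
  T = Σ(t³−t)/(12(N−1)); significance letters list the groups a metric's
  group differs from at p < 0.05, unadjusted by default with Bonferroni
  available (the annotation convention follows clinical tables, which do
  not state an adjustment).
* Forward-conditional stepwise OLS with p_enter = 0.05, p_remove = 0.10
  (conventional thresholds; the method name, not the thresholds, is
  prescribed).
* Lin's CCC with 1/n moment convention; precision = Pearson r, accuracy =
  CCC/r. CoV = 100·SD(x−y)/mean((x+y)/2), bias = 100·mean(x−y)/same —
  one of several CoV definitions in circulation; this one is documented
  and pairs with the bias definition. The reproducibility table's
  "average" row is a simple mean across metrics.
* Age grouping uses explicit bin edges when supplied, otherwise five
  equal-count quantile bins (descriptions of such cohorts use "quartiles"
  and five groups interchangeably; the bin count is a parameter).
* Systolic/diastolic KEi_EDV are *time averages* over their windows by
  default (`window_stat="peak"` switches to peaks); E/A windows split
  diastole at the KEi valley between the two largest diastolic local
  maxima, falling back to the temporal midpoint (flagged) when the peak
  structure is ambiguous.

## Problem sizes and numerical choices

Phantom checks run on 32×32×12 to 48×48×16 grids at 3 mm, 30 phases —
small enough for the whole suite and the acceptance script to complete in
minutes on one CPU while keeping boundary-voxel counts representative.
Cohort calibration uses 100 seeds of n = 53 and 1,000 null replicates.
Tie-breaks: end-systole takes the earliest minimum; boundary voxel centers
are inside; empty myocardial ROIs skip background correction with a flag
rather than failing. All simulator randomness flows from explicit seed
fields; nothing reads global RNG state.

## Known limitations

* Radius-vs-angle ray casting assumes star-shaped contours; non-star
  shapes fall back to the nearest intersection with a warning.
* Only single aliasing wraps are corrected; double wraps are flagged.
* The LPC offset estimate is constant per (slice, component) in time;
  slowly phase-varying offsets are not modelled (nor generated).
* Keyframe propagation is linear in phase; rapid volume transients between
  keyframes are smoothed, which biases mid-systolic interpolated volumes
  on the phantom by up to ~20 % locally (keyframes and the detected EDV/
  ESV extremes are unaffected).
* The valve plane does not tilt with the annulus in the generated
  phantom (landmarks stay coplanar-horizontal); oblique-plane resampling
  is implemented and unit-tested, but not exercised end-to-end.
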