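# Methods

This note records the models, conventions and numerical choices behind
`marginrad`, and what the synthetic test beds do and do not establish.

## Grid conventions

Grids are indexed `(x, y, z)` with `z` the axial axis; voxel centers sit
at integer indices and physical positions are `index × spacing` (mm).
Masks binarize at `value > 0`.  When a mask has several 26-connected
components the largest carries the shape features (a warning is emitted);
intensity statistics use every foreground voxel.  Volumes are analyzed on
their native grid — no resampling — with shape features computed in
millimetres and LoG scales in voxel units per axis, so anisotropic grids
are honoured for geometry and deliberately not for filter scales.

## 3D shape features

The surface is a triangle mesh extracted at iso-level 0.5 from the
(zero-padded) binary mask.  Two views of the mesh are used:

- **Raw marching-cubes mesh** — flat faces of digitized polyhedra stay
  exactly planar, so convexity `V/V_hull` (enclosed volume over
  convex-hull volume of the mesh) is exactly 1 for convex solids.  Max 3D
  diameter is the largest pairwise distance among hull vertices.
- **Taubin-regularized mesh** (shrink/inflate factors 0.5/0.53, 20
  iterations) — removes the voxelization staircase that otherwise
  inflates curved surface area by 7–9%.  Surface area, sphericity and
  compactness come from this mesh; a digitized r=20 ball scores
  sphericity 0.988 and a digitized ball's area lands within ~2% of
  4πr².  The Taubin update is a linear map of vertex coordinates, so the
  dimensionless features are exactly scale-invariant.

No local sub-voxel surface can simultaneously preserve sharp edges and
smooth curvature: the regularized mesh under-reports the area of small
cuboids by ~7% (edge chamfer), and mesh-derived values vary by ~1e-4
under 90° grid rotations because marching cubes resolves ambiguous
configurations orientation-dependently.  Both biases are asserted, with
these magnitudes, in the test suite rather than hidden.

The reported `volume` feature is the plain voxel count × voxel volume
(also the S/V denominator); the dimensionless descriptors use the
mesh-enclosed volume so numerator and denominator describe the same
surface.

The category contains the three margin descriptors that motivate the
package (convexity, sphericity, surface-to-volume ratio) completed to
seven with the standard morphology set (volume, surface area,
compactness, max diameter).

## 2D shape features

Computed on the axial slice of maximal in-plane area (ties → lowest
index), restricted to its largest 8-connected in-plane component:

- **Roundness factor** `4πA/P²` with A = pixel count × pixel area and P
  the length of the marching-squares contour of the Gaussian-smoothed
  (σ = 0.8 px) binary slice.  Smoothing removes the staircase that would
  deflate a digitized disk's roundness to 0.90; σ was fixed against the
  analytic calibration targets (disk → 1 within 2%, square → π/4 within
  5%).
- **Eccentricity** `sqrt(1 − λ_minor/λ_major)` from the central second
  moments of the pixel centers in physical coordinates (exact under
  in-plane 90° rotations).
- **Solidity** — area of the boundary polygon over the area of its convex
  hull.  Defining it on the sub-pixel polygon (rather than on pixel
  centers) keeps it exactly 1 for convex digitized slices and bounded by
  1 by construction.

## LoG histogram features

The LoG response is Gaussian smoothing (σ = scale, voxel units, reflect
boundaries) followed by the discrete Laplacian (sum of per-axis second
differences).  Filtering runs on the full volume *before* masking, so the
tumor's edge against the lung background contributes to in-ROI
statistics — the point of an edge-sensitive margin feature.  A fully
constant image therefore yields degenerate statistics at every scale,
while a flat-interior tumor over a distinct background does not.

Nine statistics per image version: min, max, mean, median (midpoint
convention), population SD, Fisher skewness, Pearson (non-excess)
kurtosis (normal → 3), entropy in bits and uniformity Σp², the latter two
over 64 equal-width bins spanning [min, max] with 0·log 0 = 0.  Samples
with SD < 1e-12 are flagged degenerate (skewness = kurtosis = 0, entropy
0, uniformity 1).  With the original image and six scales (1–3.5 voxels)
this gives the 63-feature category; the factorization 9 × 7 is the
natural one consistent with the category count and the named features
(min/max/median/kurtosis at scale 3, medians at 1 and 1.5), and is fixed
here as such.

## Fractal features

- **Box-counting dimension** of the 3D boundary-voxel set (foreground
  voxels with a background 6-neighbour) over dyadic box sizes 1, 2, 4, …
  up to half the bounding-box extent (≥ 3 sizes required); the dimension
  is −slope of the least-squares fit of log N(s) on log s, all sizes
  included (no adaptive window), with R² reported.  On a 41-voxel-extent
  sphere boundary the largest box saturates and the estimate lands at
  1.84, slightly below the continuum value of 2; plane and line test
  patterns recover 2.0 and 1.0.
- **Lacunarity**: gliding-box statistic `var/mean² + 1` of box mass over
  all boxes fully inside the mask bounding box, averaged over box sizes
  {2, 4, 8}; exactly 1 for translation-homogeneous solids.
- **FSD (blanket method)**: on the maximal-area slice the ROI is split by
  the Euclidean distance transform into a rim (≤ 3 px from the in-plane
  boundary) and a core.  Each region's intensity patch (other pixels held
  at the region mean) gets a blanket signature
  `S(ε) = 2 − Δlog A(ε)/Δlog ε`, ε = 1…8, where A(ε) is the
  upper-minus-lower envelope area; FSD is the mean |S_rim − S_core| over
  ε ≥ 2, and a rim that swallows the core degenerates to 0 with a flag.
  **This rim-vs-core reading is the largest interpretive choice in the
  package**: the published blanket signature compares two *images*,
  whereas a per-tumor margin feature needs a single-image contrast; the
  margin-vs-interior definition follows the package's margin focus.
  Envelope growth uses 4-neighbour max/min with edge replication, so a
  flat image has A(ε) = N exactly at every ε.

## Feature assembly, normalization, ICC

Canonical order: 7 `shape3d`, 63 `log` (statistic-major, scale-minor), 3
`shape2d`, 3 `fractal` — 76 names, asserted everywhere.  Strict
extraction fails with the list of offending extractors; lenient mode
emits NaN.

Min–max normalization maps each feature to [0, 1] per cohort; constant
columns map to 0 with a warning.  The fitted (min, max) are stored so
held-out subjects are transformed with training parameters (values
outside [0, 1] permitted).  Descriptive analyses normalize on the full
cohort; inside cross-validation the normalizer is refit per training
fold.

Reproducibility uses ICC(2,1) — two-way random effects, absolute
agreement, single rater — the standard two-rater segmentation
reproducibility index; the form is computed from the explicit ANOVA
decomposition and cross-checked against an independent reference
implementation in the tests.  ICC is computed on raw values; absolute-
agreement ICC is invariant to an affine change shared by both raters, so
normalizing first would not change it.  Band labels: ≥ 0.8 excellent,
0.6–0.799 good, < 0.6 poor.

## Prognostic models

- **LASSO selection**: L1-penalized Cox partial likelihood (or logistic
  deviance for binary labels) over a 100-value log-spaced penalty grid;
  the working penalty minimizes the mean 10-fold cross-validated held-out
  deviance (Breslow partial likelihood for Cox, log loss for logistic).
  The minimum-deviance rule (not 1-SE) is used; it over-selects somewhat,
  which the support-recovery tests treat as selection *including* the
  true support.
- **Survival model**: Cox proportional hazards (lifelines) with backward
  stepwise pruning by partial AIC; coefficients reported exponentiated
  with 95% CIs, discrimination by Harrell's C (concordant pairs /
  comparable pairs, ties 0.5).  The modelling tradition this mirrors is
  ambiguous between hazard-ratio and odds-ratio presentations of
  overall-survival models; a logistic-on-event-status variant
  (`family="logistic"`) is provided for that reading.
- **Internal validation**: 10-fold cross-validation stratified on the
  event indicator; per-fold normalization refit; held-out linear
  predictors pooled into one C-index.
- **KM stratification**: within each stratum, subjects split at the
  stratum median of the risk score (low vs high); product-limit curves
  and the two-group log-rank test per stratum; a constant risk score
  degenerates to χ² = 0, p = 1.
- **Time-dependent AUC**: cumulative-case/dynamic-control estimator with
  inverse-probability-of-censoring weights from the validation cohort's
  Kaplan–Meier censoring estimator.
- **MP model**: stratified 70/30 split; LASSO-logistic selection and an
  unpenalized logistic fit on the training side only; held-out AUC with a
  95% bootstrap CI (1000 resamples).  An empty selection degrades to an
  intercept-only model.

All randomized steps (folds, splits, simulations, bootstraps) take
explicit seeds recorded in the report.

## Synthetic data

**Phantoms** digitize analytic solids (voxel center inside → foreground):
spheres, ellipsoids, cuboids; spiculated tumors add square-cross-section
radial spikes along a seeded rotation of a Fibonacci direction lattice
(reproducible geometry even for few spikes); lobulated tumors are unions
of overlapping spheres.  Textures: constant, Gaussian noise, or an
intensity gradient, over a constant lung-like background (−800 vs +60
HU-like units).

**Cohorts** draw features as i.i.d. standard normals and clinical
covariates from declared distributions; survival times are exponential
with rate `h₀ exp(Σβx)` (default baseline 0.02/month, median ~35 months,
plausible for a resected-adenocarcinoma cohort over follow-up), censored
by an independent exponential whose rate is solved (Brent root finding)
so the expected censoring fraction matches the target; MP labels follow a
logistic link with the intercept solved for a default prevalence of
0.437, the observed frequency of the micropapillary pattern in resected
adenocarcinoma.  The exponential PH choice gives closed-form calibration
and exact concordance expectations for the test oracles.

What the synthetic beds do **not** capture: CT noise and reconstruction
physics, anatomical context, inter-feature correlation structure of real
radiomics panels, non-proportional hazards, informative censoring, and
rater-specific segmentation bias.  Passing tests establish that the
pipeline's mechanics are correct and calibrated — not that real cohort
effect sizes would be reproduced.

## Problem sizes

Defaults were chosen so the full suite and the acceptance script each run
in well under five minutes on one CPU: phantoms on 48³ grids (r = 12–20),
cohorts of 400–800 subjects for single fits, 5000 for calibration checks,
and 20 seeded replicates for the recovery rates.

## Known limitations

- Surface-area bias on sharp-edged solids (~−7%) and the single-image FSD
  definition, both discussed above.
- LoG scales are isotropic in voxel units; strongly anisotropic grids
  mix physical scales across axes.
- The penalty path of the logistic LASSO relies on scikit-learn's
  liblinear solver; coefficients below its duality-gap tolerance are
  reported as zero.
- The external-validation harness (time-dependent AUC on a held-out
  cohort) is exercised on simulated data only; no external imaging cohort
  is fetched or bundled.
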