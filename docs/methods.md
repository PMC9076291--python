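# Methods

## Scope and model

`cbbct` reproduces, on synthetic data, the measurement-and-analysis chain
used to predict pathologic complete response (pCR) to neoadjuvant
chemotherapy from dynamic contrast cone-beam breast CT: four attenuation
sweeps per exam (pre-contrast and 60/120/180 s after injection), three exams
per patient (pre-, mid-, late-treatment), fat-normalized kinetic features
and threshold-based morphometry per exam, then group comparison, ROC, and
backward-stepwise logistic modeling across the cohort. No patient data ship
with the package; a digital phantom provides exams whose feature
distributions match published pooled summaries.

### Enhancement model

All enhancement is fat-referenced. For a lesion ROI and a fat reference ROI
on the same axial slice,

    dHU(t) = (HU_lesion(t) - HU_fat(t)) - (HU_lesion(0) - HU_fat(0))

and the pre-contrast fat-corrected attenuation is
`base = HU_lesion(0) - HU_fat(0)`. The three curve summaries are

* maximum enhancement ratio `R = (base + max dHU) / base`,
* wash-in rate `100 * (max dHU / base) / T_peak` (% of baseline per second),
* washout rate `100 * ((dHU_peak - dHU_final) / base) / (T_final - T_peak)`,
  defined as 0 for persistent curves (peak at the final phase).

The normalizer is deliberately the *pre-contrast corrected attenuation*,
not the (identically zero) pre-contrast enhancement: with the published
pooled values (baseline ~205 HU, peak enhancement ~76 HU) this definition
reproduces the reported ratio magnitudes near 1.2-1.4, whereas normalizing
by pre-contrast enhancement is undefined. `T_peak` is the sampled phase time
of the maximal dHU (no interpolation); ties take the earliest phase.

### Phantom

Each exam is a uniform fat background (-100 HU; optional unenhancing
glandular blobs) containing one axis-aligned ellipsoidal lesion. A voxel
belongs to the lesion when its center lies inside the ellipsoid; noise is
additive i.i.d. Gaussian per voxel (default sd 5 HU; spatially correlated
CT noise texture is out of scope). The lesion's post-contrast attenuation
scales its fat-corrected baseline by `1 + (R_true - 1) * frac(t)`, where
`frac` is the fraction of peak enhancement attained at each sampled phase.
`frac` is piecewise linear by default, but a lesion may carry explicit
per-phase uptake fractions. That freedom is load-bearing: the published
pooled summaries (density 204.7 +/- 42.4 HU, one-minute enhancement
75.8 +/- 39.1 HU, ratio 1.42 +/- 0.202, wash-in ~0.24 %/s) cannot all arise
from a *linear* rise, because a linear rise rigidly ties the 60 s
enhancement to the wash-in rate (`E[dHU_60] = 0.6 * base * washin`, about
44 HU — far from 75.8). A concave early uptake, which is also the
physiologically typical shape for enhancing carcinomas, decouples the two.

Default pre-treatment calibration (one draw per lesion):

| quantity | distribution | rationale |
|---|---|---|
| baseline density | N(204.7, 42.4) HU, truncated [80, 400] | published pooled mean/sd |
| largest diameter | N(41.3, 19.1) mm, truncated [6, 110] | published pooled mean/sd; upper bound = field of view |
| other two axes | uniform 0.55-0.95 of the largest | mildly oblate lesions; longest axis in-plane |
| peak ratio R | N(1.42, 0.202), truncated [1.05, 2.2] | published pooled mean/sd; lower bound = minimum detectable enhancement |
| peak time | 180 s w.p. 0.95, 120 s w.p. 0.05 | centers the implied wash-in mean at ~0.25 %/s against the published 0.24 |
| 60 s uptake fraction | N(0.572, 0.15), truncated [0.05, 1] | centers measured one-minute enhancement at 75.8 HU given the ratio and density calibrations |
| 120 s uptake fraction | N(0.82, 0.10), truncated [frac60, 1] | monotone concave rise |
| washout fraction | U(0.05, 0.35) when the peak is at 120 s, else 0 | mostly persistent curves, consistent with the small pooled washout rate |

Longitudinal change multiplies each axis by a per-timepoint linear
shrinkage factor and `R - 1` by an enhancement-decline factor, both drawn
per patient from response-group normal distributions. The published tables
pool the two groups, so the group separations are free parameters; the
defaults (responders: shrinkage factor 0.62/0.40 and enhancement factor
0.50/0.15 at mid/late; non-responders 0.85/0.75 and 0.85/0.70) were fixed
once so that the responders' late volume reduction regime brackets the
~86% reduction cutoff reported for seven-cycle response (0.40^3 => ~94%
reduction vs 0.75^3 => ~58%). Covariates (age, laterality, ER/PR/HER2,
Ki67 class) are sampled independently of the imaging phenotype; Miller-Payne
grade is 5 exactly for simulated responders and 1-4 (0.10/0.25/0.40/0.25)
otherwise.

Each patient can be realised as rendered voxel volumes or as the
analytically known feature values (`simulate_cohort_table`); both paths
share one sampling routine. The tabular path exists because power and
selection studies need hundreds of cohorts, which would be voxel-rendering
bound for no benefit: the rendered path is validated separately against the
tabular truth (measured-minus-true biases are below 1 HU / 1 mm / 0.01 in
ratio at the default noise level).

### Measurement

Segmentation thresholds the enhancement image (strongest-enhancing phase
minus pre-contrast) at the Otsu value (operator-editable in the original
workflow, hence configurable here), keeps the largest connected component
after one binary opening, and discards components under 10 voxels as noise.
A maximal enhancement under 10 HU means no measurable lesion: the mask is
empty, all size features are 0, and the baseline-relative reduction is
100%, which keeps complete responders in the late-treatment analysis.

The lesion ROI for densities is the axial slice of maximal mask area (ties:
lower index); the lowest decile of pre-contrast voxels in that ROI is
excluded to approximate the reading rule of avoiding visible necrosis
(configurable off). The fat ROI is a fixed corner region guaranteed to be
adipose in the phantom. Diameter is the maximal pairwise distance between
boundary-voxel centers on that same slice. Calculated volume is
`pi/6 * d1 * d2 * d3` (the `0.5 * l * w^2` variant is available) with the
in-plane maximal extent, the area-equivalent conjugate diameter, and the
through-plane extent as the three diameters. Segmented volume is voxel
count times voxel volume. Surface area is measured on a marching-cubes
iso-surface of the lightly smoothed (Gaussian, sigma 0.8 voxel) indicator
at level 0.5 — voxel-face counting would overestimate smooth surfaces by
tens of percent; the smoothing anti-aliases the staircase (a 20 mm sphere
at 0.273 mm voxels meshes within ~1% of 4*pi*r^2). Masks too small to
survive smoothing fall back to the raw indicator so single-voxel masks
retain a positive area.

### Statistics

* Continuous two-group comparisons: Shapiro-Wilk gate per group at alpha
  0.05 (the original analysis does not state its gate; this is the
  conventional choice) selecting Welch's t-test when both groups pass,
  Mann-Whitney U otherwise; groups under 3 observations force Mann-Whitney.
* Categorical: Pearson chi-square, or Fisher's exact test for 2x2 tables
  with any expected count <= 5 (inclusive, so borderline-sparse tables get
  the exact test). Yates continuity correction is off by default and
  exposed as a flag; no exact test is attempted for sparse 2xk tables with
  k > 2 (a warning is emitted).
* ROC: empirical curve; AUC by trapezoid (equal to tie-half-credit pair
  concordance); operating point by Youden's J (the reported
  cutoff/sensitivity/specificity triples imply a single-point rule and
  Youden is the standard one); AUC confidence interval and the test against
  0.5 from the DeLong placement-value variance; anti-predictive scores are
  auto-oriented and the orientation reported.
* Paired AUC comparison: DeLong's test via placement-value covariance,
  two-sided normal p; degenerate variance returns p = 1.
* Logistic modeling: maximum-likelihood fits (Newton, BFGS fallback);
  odds ratios `exp(coef)` with Wald SE/CI/p. The multivariable model is
  backward stepwise: candidates are the univariably significant predictors
  (p < 0.05), and the largest-Wald-p predictor is removed while it exceeds
  `alpha_remove` (default 0.05). Exactly collinear candidates are dropped
  up front with a warning; predictors with undefined Wald p (separation,
  non-identifiability) count as evidence-free (p treated as 1). Perfect
  separation is flagged rather than hidden. The pipeline standardizes
  predictors by default, so its odds ratios are per SD. No multiplicity
  correction is applied by default (matching the original workflow); Holm
  adjustment is available behind a flag.

Model performance is apparent (in-sample), matching the original report;
cross-validation/external validation is deliberately out of scope.

## Problem sizes and numerical choices

* Calibration cohort: 200 exams on a 128-voxel cube at 1.0 mm. This field
  of view holds the full diameter distribution (up to ~11 cm) untruncated;
  at these lesion sizes the measured quantities (ROI means, in-plane
  lengths) are insensitive to refining the grid to 0.5 mm, and a 200-exam
  cohort renders in about a minute. Sub-millimeter grids remain available
  via `AcquisitionSpec` (geometry oracles run at the native 0.273 mm).
* Truncation of the sampling distributions shifts the means slightly
  (diameter +~1.3 mm, ratio +~0.016); these shifts are well inside the
  three-standard-error calibration tolerances and are accepted rather than
  re-centered.
* Power/selection studies: 50 replicate cohorts of n = 80 for the
  longitudinal significance pattern; 100 replicate cohorts of n = 200 for
  stepwise selection recovery; 1000 replicates for type-I error checks.
* The qualitative pattern is operationalized per cohort as: at most 2 of
  the 11 continuous parameters significant pre-treatment (the expected
  false-positive allowance; P(<=2 | 11 independent 5% tests) ~ 0.985), all
  six key size/enhancement parameters significant late, and washout
  non-significant (the pattern preset pins every peak at 180 s so washout
  is uninformative in both groups by construction).
* Determinism: every stochastic routine takes a seed or NumPy Generator;
  cohorts use `SeedSequence.spawn` per patient, so results are reproducible
  bit-for-bit and independent of patient processing order.

## What the phantom does and does not show

The phantom has sharp lesion boundaries, uniform intra-lesion attenuation,
uncorrelated noise, axis-aligned ellipsoidal geometry, and covariates
independent of imaging phenotype. Passing tests therefore demonstrate that
the measurement and inference chain is correct and internally consistent —
that true lesion properties survive rendering, segmentation, and ROI
measurement, and that the statistical machinery has its nominal operating
characteristics. They do not demonstrate segmentation robustness to
irregular margins, necrosis, non-mass enhancement, partial-volume or
beam-hardening effects, nor clinical-level predictive performance, which
can only be assessed on patient scans that are not publicly available.

## Known limitations

* Single lesion per patient (the largest-lesion rule is honored by the
  largest-connected-component step, but multifocal disease is not modeled).
* No projection-domain physics (scatter, beam hardening, reconstruction
  artifacts) and no breast compression or calcification modeling.
* Sparse 2xk (k > 2) tables fall back to asymptotic chi-square.
* Wald inference throughout; no profile-likelihood or Firth correction for
  separated fits (they are flagged instead).
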