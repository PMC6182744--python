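# Methods

`ostex` implements a subchondral-bone MRI texture-analysis study design as
a reusable pipeline: texture feature extraction over manually drawn
subchondral ROIs, inter-observer reproducibility screening, construction of
a progression-defined matched case-control cohort, and a composite texture
score built by repeated cross-validated LASSO logistic regression.  Because
the clinical images the design was developed for (coronal-oblique 3D FISP
MRI of the knee, from an osteoarthritis progression cohort) cannot be
redistributed, the package ships a synthetic trabecular-texture study
generator so that every stage runs, and is tested, end to end.

## Texture features

Each knee/timepoint is represented by its five most central coronal slices
(configurable), each with a medial tibial and a medial femoral subchondral
ROI.  Within an ROI, in-mask intensities are binned by min-max equal-width
quantization — 4 bits (16 grey levels) for gradient features, 6 bits (64
levels) for co-occurrence and run-length features.  Bin edges are half-open
with the top edge closed, so the ROI minimum maps to level 1 and the
maximum to the top level; this makes every feature invariant to positive
affine intensity rescaling (scanner gain).  A ±3σ window is available as a
config alternative (`quantize_normalization="sigma"`); the min-max window
is the default because it is the common radiomics choice and is exactly
oracle-checkable.

Four feature classes are computed per ROI per slice:

* **Histogram** — population mean, variance, skewness (m₃/σ³) and excess
  kurtosis (m₄/σ⁴ − 3) of the in-mask intensities, min-max normalized to
  [0, 1] by default (`histogram_normalize="none"` uses raw units).
* **Absolute gradient** — on the 4-bit grid, the central-difference
  gradient magnitude G = √(ΔI_row² + ΔI_col²) over interior pixels (all
  four neighbours in-mask); features are the four moments of G plus the
  fraction of interior pixels with G > 0.
* **Run-length matrix (RLM)** — maximal same-level runs along the
  horizontal, vertical, 45° and 135° directions; mask gaps terminate runs.
  Galloway features: short/long-run emphasis, grey-level and run-length
  non-uniformity, fraction of pixels in runs; each averaged over the 4
  directions.
* **Grey-level co-occurrence matrix (GLCM)** — symmetric pair counts for 4
  directions × 5 offsets (20 configurations), both pixels in-mask.
  Haralick features (angular second moment, contrast, correlation, sum of
  squares, inverse difference moment, sum average, sum entropy, entropy,
  difference entropy; natural log), computed per configuration and averaged
  over the 20 configurations.  Configurations with no valid pairs are
  skipped and excluded from the average.

Per-slice values are averaged (unweighted) over slices into one summary
value per subject, region and timepoint; change columns are follow-up minus
initial.  Averaging happens at the *feature* level (feature per
configuration, then mean), not by averaging matrices.

The default registry holds 19 features: all histogram, gradient and RLM
features plus the five most widely reported GLCM features (ASM, contrast,
correlation, inverse difference moment, entropy).  All 23 implemented
features can be selected via `TextureConfig(registry=...)`; the seven
features named in the study design's result tables (mean, variance,
Gr. mean, Gr. variance, contrast, ASM, entropy) are mandatory registry
members.

## Reproducibility screening

Duplicate analyses by two independent raters give an n×2 table per feature
and region.  Agreement is summarized by ICC(A,1) — two-way random effects,
absolute agreement, single measures, computed from explicit ANOVA mean
squares — and by the root-mean-square average coefficient of variation
(RMSCV), with the within-subject sample SD convention (two ratings a, b →
SD = |a−b|/√2).  Subjects whose |mean rating| falls below 1e−8 times the
feature scale are excluded from the RMSCV (CV is ill-defined near zero,
e.g. for sign-crossing skewness).  A feature is retained only if ICC ≥ 0.8
and RMSCV ≤ 10 % in *both* regions; the boundary values are retained
because exclusion is strictly "< 0.8 or > 10 %".  Note the ICC(A,1)
estimator is bounded above by 1 but can fall below −1 on pathological
tables; the screen only cares about the upper range.

## Cohort construction

Radiographic progression is a decrease in minimum medial tibiofemoral
joint space width (minJSW) of ≥ 0.7 mm between the 36- and 72-month
visits; the boundary is inclusive (a 1e−9 mm tolerance guards against
binary floating-point artifacts such as 3.8 − 3.1 < 0.7).  Subjects with a
missing minJSW at either visit are ineligible.  Eligibility also excludes
KL grade-4 knees (ceiling effects) and knees with a strictly greater
lateral than medial OARSI JSN grade (lateral-predominant disease); ties
are retained.

Cases are matched 1:1 to controls on age, sex, BMI and initial minJSW.  A
logistic propensity model gives each subject a logit-scale score; the
assignment is solved exactly as a linear assignment problem (global
total-distance minimum, not greedy).  The pair distance is
|Δ logit propensity| plus an equally weighted Euclidean distance on the
standardized covariates.  The covariate term matters: the propensity index
is one-dimensional, and matching on it alone leaves each covariate's
post-match standardized mean difference at the √(2/n) sampling-noise floor
(0.10–0.22 at 61 pairs in our simulations); breaking propensity near-ties
by covariate closeness brings all four covariates below 0.1.
`mahalanobis_weight=0` restores pure logit matching.  No caliper is
applied.  After post-matching exclusions (motion artefact, missing MRI,
cysts, surgery), an excluded case removes its control, and an excluded
control is replaced by the nearest unused reserve control for its case.

## Composite texture score

For each of six datasets (tibial, femoral, combined × initial, 12–18-month
change), case status is modelled by L1-penalized logistic regression on the
standardized retained features.  The penalty grid is 100 log-spaced values
from λ_max (the smallest penalty that zeroes all coefficients) down to
10⁻³ λ_max; λ* minimizes the 10-fold cross-validated misclassification
error at the 0.5 probability threshold, with ties resolved toward the
larger penalty.  Because folds are random the procedure is repeated (100
iterations by default); the representative iteration is the one whose CV
error is closest to the mean CV error (ties to the lowest index) — a
typical rather than a lucky model — and its full-data refit defines the
composite score, the standardized linear predictor.  The c-statistic is
the mean cross-validated AUC over iterations, with an across-iteration
normal CI (mean ± 1.96·SD/√n_iter); with stable folds this CI is nearly
degenerate, which is why intervals like 0.68 (0.68, 0.68) arise.

The solver is an in-package batched FISTA proximal-gradient path solver
(exact per-problem Lipschitz steps from the eigendecomposition of the
weighted Gram matrix, adaptive restart, warm starts across the descending
grid; the intercept is unpenalized, matching the glmnet
parameterization).  Batching all folds of all iterations into one path
solve is what makes 100 repetitions × 10 folds × 6 models affordable on one
CPU.  Solutions were verified against R glmnet coefficients (to ~1e−7) and
against the KKT conditions; CV error curves use a looser solver tolerance
(1e−4) than coefficient refits (1e−7), which leaves fold error counts
unchanged.

### Association estimates and significance

The odds ratio per 1 SD of score (univariable logistic fit, Wald 95 % CI)
is reported for the in-sample composite score, as the descriptive estimate
of association strength.  This estimate is **optimistic**: the penalty was
selected on the same subjects.  Our null simulations quantify how severe
this is — on zero-effect data (n = 122, 12 features) the in-sample
likelihood-ratio test is below the adjusted 0.008 threshold in about two
thirds of runs, and even pooled out-of-fold scores remain anti-conservative
(the variance of corr(score, y) is inflated ~2.3× because every subject's
label enters the other folds' training sets; fold-stratified permutation
does not repair this).

Significance is therefore assessed by a held-out test that is calibrated
by construction: for each of 9 stratified half-splits, the penalty is
selected and the model refit on the training half only; the untouched half
is scored, and an exact permutation test of the score–outcome association
is computed within it.  The per-split p-values are combined with the
twice-the-median rule, which is a valid p-value under arbitrary dependence
between splits.  In simulation this test shows zero false positives in 240
null runs while detecting a strong texture signal in 100 % of runs.  A
held-out OR (median across splits) is reported alongside.  Models are
called significant at p < 0.008, the Bonferroni-style threshold for six
primary models (0.05/6 ≈ 0.0083).

A representative model with all-zero coefficients is flagged as a null
model: its score is constant, no OR is reported, and p = 1.

## Synthetic studies

Images are thresholded Gaussian random fields: white noise smoothed at a
correlation length ℓ (pixels), thresholded at a quantile (default 0.5) to
a binary trabecular pattern, rendered at plate/marrow intensities 1000/200,
blurred (σ = 0.6 px) and corrupted by Rician noise (channel SD 40), as in
magnitude MRI.  ℓ is the single "spatial organisation" knob: large ℓ gives
coarse organised plates (low GLCM entropy, long runs), small ℓ fine
disorganised texture.  This is a texture model, not a claim about
trabecular physics.  ROIs are rectangular bands above (femur) and below
(tibia) a synthetic joint line, ~1 cm-equivalent deep; duplicate-rater
masks are produced by translating the band by a rounded N(0, jitter)
offset and randomly growing/shrinking it one morphological step.

Covariates follow the emulated study's participant table: age ~ N(64.5,
8²) years, BMI ~ N(31.2, 4.7²) kg/m², 42 % female, initial minJSW ~
N(3.8, 1.2²) mm; minJSW change N(−1.29, 0.63²) mm for cases and
N(0, 0.44²) for controls, resampled until consistent with the 0.7 mm rule
(`strict_labels`); KL and OARSI JSN grades at the observed frequencies,
with lateral ≤ medial so generated subjects are eligible by construction.
Progressors draw a baseline ℓ deficit (`ell_group_delta`, default 0.15 px)
and an additional follow-up ℓ loss (`ell_change_delta`, default 0.25 px)
against a between-subject spread of 0.25 px — a modest effect chosen to
mimic the moderate discrimination (c-statistics 0.6–0.7) the design was
built around.  `CohortParams.zero_effect()` removes both deltas;
`CohortParams.strong_effect()` sets the follow-up loss to 1.0 px (4
between-subject SDs), the regime where the change models should approach
ceiling discrimination.  Everything is deterministic given (parameters,
seed); default image size is 256 px (a desk-scale stand-in for the 1024 px
interpolated acquisitions) with 5 slices.

What the generator does *not* emulate: real trabecular microarchitecture
and its anisotropy, partial-volume and coil-shading effects, inter-slice
correlation beyond a shared ℓ, ROI-drawing errors correlated with anatomy,
and any true dependence of texture on the matching covariates.  Passing
tests therefore demonstrate that the pipeline recovers the kind of signal
the generator encodes — a group difference in spatial organisation — not
that it would detect the (much subtler) clinical effect.

## Problem sizes in the test suite

The test suite and acceptance script run everything at desk scale, chosen
once as the package's own test conditions: oracle sweeps on ≤10×10 masked
grids; study-level tests with 48–64 px images, 2–3 slices and 12–61 case
cohorts; repeated-LASSO settings reduced to 20 iterations and a 30-value
penalty grid in study-level tests (the defaults remain 100/100).  Null
calibration uses 10 zero-effect studies at the full 61-pair cohort size
(60 model p-values — ample for a test whose statistic is exactly
calibrated); signal recovery uses 20 strong-effect studies at 12 pairs.
The acceptance script fits the full 100-iteration procedure on a 30-pair
strong-effect study.

## Known limitations

* The exact 19-feature registry of the original texture software is not
  public; the default registry is a reasoned choice and is configurable.
* The in-sample OR overstates association strength by design; use the
  held-out OR and p for inference.
* Gradient features require ROIs at least 3 pixels thick.
* The generator's rater-jitter model produces agreement patterns that are
  uniform across features; real inter-observer error is feature-specific.
* One knee per participant; no time-to-event analysis; no DICOM ingestion.
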