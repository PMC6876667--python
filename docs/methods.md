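# Methods

`neurosem` re-implements, as a tested library, a latent-variable analysis
pipeline for large brain-structure / intelligence studies: a general
cognitive factor *g* is measured by confirmatory factor analysis (CFA) over
four heterogeneous cognitive tests, and its standardized associations with
global and regional MRI-derived phenotypes are estimated inside structural
equation models fitted by full-information maximum likelihood (FIML).
Because the motivating data (a large biobank imaging cohort) are
access-restricted, the package ships a synthetic cohort generator whose
default parameters are the published population values; every stage of the
pipeline is exercised and validated against that generator.

## The measurement model

The four indicators are Matrix Reasoning (integer 0–15), Symbol-Digit
Substitution (non-negative integer), Verbal-Numerical Reasoning (integer
0–13) and Trail-Making part B completion time in deci-seconds (positively
skewed; loads negatively because a slower time means worse performance).
The one-factor model is

  y_ij = nu_j + gamma_j' c_i + lambda_j g_i + eps_ij,   Var(g) = 1,

with covariates c (age, sex; head-position x/y/z for MRI variables)
attached to the manifest variables *inside* the model.  A residual
covariance between Matrix Reasoning and Verbal-Numerical Reasoning is
admitted when modification indices demand it (see *Respecification*).
Variance explained by *g* is the mean squared standardized loading.

## Estimation

The engine holds models in RAM form over v = [observed endogenous;
latents]: v = nu + A v + G x + zeta, Cov(zeta) = S, with fixed exogenous
regressors x.  Conditional moments are mu(x) = F(I−A)^−1(nu + Gx) and
Sigma = F(I−A)^−1 S (I−A)^−T F'.

* **FIML.** Each subject contributes the normal log-density of their
  observed sub-vector.  Subjects are grouped by missingness pattern and the
  likelihood is evaluated from per-pattern cross-product matrices, so one
  evaluation costs O(patterns × p³) regardless of n; pattern grouping is
  exactly equivalent to per-subject evaluation (tested).
* **Fixed-x conditioning.** Covariates — and, in prediction models,
  complete brain predictors — enter as fixed regressors.  For complete
  predictors this conditional likelihood is exactly equivalent to ML with a
  saturated exogenous block, and is what makes 48-predictor MIMIC training
  models cheap.
* **Optimizer.** L-BFGS-B on −loglik/n with 3-point numeric gradients
  (ftol 1e−12, gtol 1e−7); variables are internally z-scaled and estimates
  mapped back, so results are invariant to indicator rescaling (tested to
  1e−6).  Non-positive-definite proposals are penalized proportionally to
  the eigenvalue violation rather than with a flat cliff, and abnormal
  line-search exits trigger a warm restart.
* **Degenerate inputs.** Under null populations the one-factor model has a
  likelihood ridge of single-indicator Heywood solutions.  Residual
  variances are unbounded by default (Heywood cases are flagged, not
  suppressed; a bounded mode exists), and when the optimizer lands on a
  degenerate solution the fit is retried from near-zero loadings, keeping
  the non-degenerate optimum if it is within 2 log-likelihood units (one
  parameter's worth of chance improvement).
* **Standard errors** come from the observed information (central-difference
  Hessian, step 1e−5·max(1,|θ|)); standardized-solution SEs by the delta
  method with numeric Jacobians.

## Fit assessment and inference conventions

The model chi-square is 2(l_saturated − l_model), where the saturated
conditional model is estimated by EM over missingness patterns (closed form
for complete data).  The baseline model for CFI/TLI keeps the covariate
regressions and free means but zeroes all covariances; with missing data it
factorizes into per-variable univariate regressions (closed form).
Conventions, also recorded in `FitResult.meta`:

* RMSEA uses the N divisor: sqrt(max(chi2 − df, 0)/(df·N));
* saBIC = −2l + k·ln((N+2)/24); AIC = −2l + 2k;
* SRMR is the covariance-only variant against the saturated moments;
* identification fixes latent variances to 1 (all loadings free), so
  standardized loadings are directly comparable across models;
* the standardized solution is on the **covariate-partialled metric**:
  variances exclude the covariate contribution, so a standardized path is
  per SD of the covariate-adjusted variables.  This is the metric on which
  the generator's parameters are defined, making recovery exact in
  expectation.

**Modification indices** are univariate score (Lagrange-multiplier) tests
for fixed residual covariances: MI = s²/v with the observed score s and
v the Schur complement of the candidate in the normal-theory *expected*
information.  Expected rather than observed information is used because
under gross misspecification the observed information loses definiteness
and overstates the chi-square drop; with the expected information the MI
tracks the actual refit drop within ~10% at large n (tested).

**Nested comparisons** report Δchi2 (with p from the chi-square upper
tail), ΔAIC and ΔsaBIC, constrained minus free.

**Invariance testing.** Weak invariance constrains the four loadings equal
across groups while freeing the second group's latent variance (Δdf = 3);
strong invariance additionally equates intercepts while freeing the second
group's latent mean (Δdf = 6).  These counts reproduce the published
Δchi2(3) and Δchi2(6).  Moderation tests set the loadings equal (weak
invariance imposed), free the second-group latent variance, and compare
free versus equality-constrained brain paths: Δdf = the number of
constrained paths (1 for the TBV model, 5 for the five-measure model; the
motivating study reports 7 df for the latter comparison, whose two extra
constraints its text does not identify).  When grouping by age, age is
dropped from the covariates; likewise sex.

**FDR families** are exactly: the 6 global bivariate tests; the
simultaneous path set; 96 cortical; 27 FA; 27 MD; 14 subcortical
(Benjamini–Hochberg step-up via statsmodels, verified against an explicit
enumeration).

## MIMIC models

Global and prediction models regress *g* simultaneously on several brain
measures (MIMIC orientation: for a single standardized predictor the path
equals the latent correlation).  TBV is excluded from the global predictor
set (part–whole overlap with the tissue volumes).  Predictor residual
covariances are **free by default** — the standard treatment of exogenous
covariances in SEM software, and the configuration a diagonal-start
MI-respecification loop converges to anyway on realistically correlated
volumes (intercorrelations ~0.6+, where a diagonal start is so misspecified
that score tests degrade).  The capped MI loop remains and runs whenever
fit thresholds (CFI, TLI > 0.95; RMSEA, SRMR < 0.05) are unmet; a
`predictor_covs="diagonal"` start is available.

## Out-of-sample prediction

Left/right homologues are averaged before training (single side used if one
is missing).  A MIMIC SEM on the training site (complete-ROI subjects,
fixed-x conditioning; covariates age, sex and head position attached to the
cognitive manifests and partialled out of the standardization metric)
yields standardized beta weights; the composite is the weight-sum of
training-standardized ROI z-scores.  Evaluation fits a two-sample SEM with
g loadings and the MR–VNR residual correlation fixed across sites (second
site's latent variance free) and the composite–g path free per site.  TBV
correction comes in two variants: residualizing each ROI on TBV inside the
training model before weights are estimated, or entering TBV as a covariate
in the structural regression at evaluation; attenuation percentages are
reported alongside.

## The synthetic cohort generator

Defaults are the published values wherever printed: loadings (0.505, 0.479,
0.592, −0.666) with MR–VNR residual correlation 0.170 (covariate-partialled
metric); global paths TBV 0.276, GM 0.281, NAWM 0.246, WMH −0.106, gFA
0.090, gMD −0.066; tract-class mean paths (FA/MD) thalamic 0.078/−0.091,
association (incl. forceps minor) 0.062/−0.049, projection (incl. forceps
major) 0.039/0.027; thalamus 0.251/0.256 and amygdala 0.075/0.062, the
other subcortical paths inside the reported 0.105–0.165 band; 16 cortical
regions at reported magnitudes (insula 0.194/0.205, frontal pole ~0.21,
…), the remainder at the reported cortical mean 0.116.  Demographics and
the three-site structure follow the published participant table (ages
truncated-normal 44–81, site-specific means; 51.8% female).

Structural features:

* Tract values load on a modality-wide factor (loading 0.7) correlated with
  g at the gFA/gMD path, plus a tract-specific g path set so the total
  equals the class mean, plus an L/R homologue factor (0.35, sign-flipped
  between FA and MD).  Regional volumes share a family factor, a bilateral
  pair factor and a slice of the TBV-specific residual, so TBV correction
  is consequential.
* Global volumes have residual correlations (TBV–GM 0.92, TBV–NAWM 0.82,
  GM–NAWM 0.65, NAWM–WMH −0.15) chosen for realism and verified positive
  semi-definite; NAWM and WMH generate WM = NAWM + WMH so the identity
  holds exactly.
* Covariate effects are defaults the motivating study does not report, chosen to make
  adjustment consequential: volumetric age effect −0.2 SD/decade, male
  volumes +0.30 SD, small head-position effects; per-test cognitive age
  effects (−0.18, −0.38, −0.05, +0.40 per SD of age for MR, SDS, VNR, TMTb
  time) reflect the steeper ageing of speeded scores.  This differential
  (non-rank-1) age structure is what makes the *uncorrected* CFA miss the
  fit thresholds (TLI ≈ 0.89, RMSEA ≈ 0.078 at full size) so that the
  MI-respecification path — which then selects the MR–VNR pair — is
  genuinely exercised, and it reproduces the qualitative inflation of the
  published uncorrected loadings for the speeded tests.
* Skewed variables: TMTb time (log-normal, median 496 ds, sigma 0.349 from
  the published median/IQR) and WMH (log-normal, median 2622 mm³, sigma
  0.95).  Exponentiating a latent normal attenuates every linear
  correlation by kappa = sigma/sqrt(exp(sigma²)−1) (exact under joint
  normality); the generating paths are divided by kappa so observed-scale
  correlations hit their targets.  Integer binning of the cognitive scores
  is applied after correlation targets are set; its <1% attenuation is
  accepted and covered by test tolerances.
* Missingness is MCAR by construction (blocks assigned independently of all
  generated values, so FIML is consistent).  The marginal availabilities of
  the published participant table and the published MRI∩cognition overlap
  of 18,426/29,004 are not jointly attainable with independent blocks, so
  blocks are nested/conditional: MRI availability by site (the third site
  has none), diffusion MRI nested within MRI (0.907), VNR probability
  conditional on MRI (0.906 / 0.986), the enhanced battery nested within
  VNR (0.576).  Expected overlap is 18,426 exactly.  A per-test refinement
  of enhanced-battery missingness and any outcome-dependent dropout are
  deliberately not modelled.
* `overlap_sample_spec` emulates the MRI-with-cognition *analysis sample*
  (MRI for everyone, VNR at 99.4%, enhanced battery at 44%), matching the
  published complete-data counts of the association models.

What passing tests on this generator do **not** show: robustness to
non-ignorable missingness, to site-dependent measurement bias, to
non-linear brain–g relations, or to the messier residual structure of real
imaging phenotypes (the generator's factor structure is exactly as stated
above, so real-data fit indices will generally be worse).

## Data cleaning

Trail-Making times coded 0 ("trail not completed") become missing; values
beyond ±4 SD of their variable's raw mean become missing (moments computed
once on the raw distribution — pass `CleaningReport.moments` back in to
make repeated cleaning idempotent); NAWM is recomputed as WM − WMH with
negative differences flagged and set missing.  On default synthetic cohorts
every per-variable trim fraction is below 1%.  The age split balances the
two groups on the cognitive–MRI overlap (ties at the boundary go to the
middle-aged group); on default cohorts the boundary falls near the
published 63.29 years.

## Problem sizes used by the checks

Analytic targets are exact arithmetic on the published loading vectors.
Recovery targets average bivariate FIML fits over 12 (script) or 4 (test
suite) replicate cohorts at the published analysis-sample sizes (n =
18,426; n = 19,000 for the subcortical scan), which puts the Monte-Carlo SE
of the mean near 0.003–0.006 against a ±0.02 recovery band.  Recovery fits
run on the generated cohorts without the ±4 SD trim: the cohorts are
generated artifact-free, and trimming a calibrated log-normal tail (WMH)
removes the low-correlation extreme tail and sharpens the observed
correlation ~7% past its target, whereas untrimmed recovery is unbiased
(verified over 30 replicates).  The trim rule exists for artifact-bearing
real data and remains part of the pipeline proper.  Calibration
checks use 500 replicates at n = 2,000; the end-to-end check runs the whole
pipeline at scale 0.1 (n ≈ 2,900).

## Known limitations

* Estimators: ML/FIML only — no robust or weighted-least-squares variants,
  ordinal thresholds, Bayesian or regularized estimation.
* Modification-index candidates are residual covariances (the only class
  the pipeline frees); cross-loadings are not scored.
* The saturated EM and the baseline closed form assume the fixed-x
  covariates are complete; rows with missing covariates are dropped with a
  count.
* Factor scores (gFA/gMD) use the regression method; their shrinkage (SD
  < 1) matches the published descriptives qualitatively, not numerically,
  since tract-level loadings are not reported for the motivating study.
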