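# Methods

This note documents the statistical machinery in `voxelgrowth`: the models,
the estimation choices, what the synthetic cohorts do and do not emulate,
and the numerical decisions a maintainer would want written down.

## The conditional latent growth model

For a single outcome series (one voxel's Fisher-z connectivity, or a
cognitive index) over T waves, the model is a linear growth SEM:

```
y_it = η_I,i + λ_t η_S,i + ε_it              ε_it ~ N(0, θ_t)
η_I,i = α_I + γ_I·m m_i + γ_I·a a_i + ζ_I,i
η_S,i = α_S + γ_S·m m_i + γ_S·a a_i + ζ_S,i  (ζ_I, ζ_S) ~ N(0, Ψ)
```

* **Wave coding.** λ = (0, 1, …, T−1): one unit of latent slope is the
  change per measurement occasion (≈ 18 months in the emulated design),
  and λ₁ = 0 centers the intercept at wave 1. The coding is a parameter
  (`loadings=`); re-coding in months rescales (α_S, γ_S·, ψ_SS) by the
  reciprocal (squared for the variance) and leaves the likelihood and all
  fit indices unchanged — a property the test suite asserts.
* **Covariates.** m (MFQ-FoF on the 0–6 scale, baseline only) and a
  (baseline age − 70). They enter as exogenous variables with a saturated
  mean/covariance block inside the joint normal; algebraically the
  conditional likelihood of y given x does not involve the x moments, so
  they are profiled out at their sample MLE. Covariate missingness is
  unsupported by design.
* **FIML.** Subjects are grouped by missingness pattern; each contributes
  the marginal normal density of its observed waves. This is the correct
  likelihood under missing-at-random dropout. With complete data it reduces
  exactly to the multivariate-normal ML (asserted in tests).

## Estimation

The log-likelihood gradient is analytic (chain rule through the structured
mean and covariance, with the pattern loops JIT-compiled); the optimizer is
a quasi-Newton iteration seeded with the observed information evaluated at
a method-of-moments start, falling back to scipy's BFGS when it stalls.
The moment start solves the growth decomposition of the saturated residual
covariance by least squares on its off-diagonal entries — exact for a
3-wave linear model — so most fits converge in a handful of steps.
Convergence requires the max-norm of the gradient to fall below 1e−7 ×
max(1, |logL|); the criterion is relative so large-N fits are not
spuriously rejected. `n_starts` deterministic jittered restarts (default 3
for single fits, 1 in the voxelwise driver) guard against local optima.
The analytic gradient is itself validated against central finite
differences in the test suite.

Standard errors are observed-information: the numerical Hessian of the
negative log-likelihood (central differences of the analytic gradient) at
the optimum, inverted. Wald z and two-sided normal p-values follow.
Variance parameters are deliberately *unconstrained* during optimization so
that negative (Heywood) estimates are observable.

**Heywood rule.** After a converged fit, any negative residual or latent
disturbance variance whose 95% Wald interval covers 0 is treated as
sampling error at the boundary: it is fixed to 0 — together with any free
covariance attached to a zeroed latent disturbance, to keep Ψ admissible —
and the model refit (warm-started), iterating until no new violation
appears. A negative variance whose interval excludes 0 is flagged
inadmissible and left alone. Each constraint raises model df by one.

**Fit indices.** χ² = 2(logL_sat − logL_model) against the FIML-saturated
model, whose MLE is computed by EM over the joint (y, x) vector (the EM
solution is cross-checked against direct maximization in tests). The CFI
baseline frees outcome means and variances, zeroes all covariances, and
keeps the covariate block saturated, so its per-outcome pieces are closed
form. RMSEA = √(max(χ²−df, 0)/(df·N)) with N (not N−1, configurable), so
χ² ≤ df forces RMSEA to 0 — at N = 69 with df = 3 this happens for most
well-fitting voxels, and the RMSEA ≤ .10 criterion alone still rejects
~17% of correctly specified models (P(χ²₃ > 5.07)). The 95% RMSEA interval
comes from root-finding on the noncentral-χ² cdf; the voxelwise driver
skips it since the interval volumes are not part of the statistic maps.
SRMR is computed over covariance residuals only (means excluded,
configurable), standardized by saturated SDs, across the full joint vector
(the exogenous block contributes zero residuals); FIML-SRMR conventions
differ across packages, which is why the definition is pinned down here and
in the frozen-oracle comparison.

**Standardization** follows the std.all convention: paths scaled by
SD(predictor)/SD(outcome) using model-implied latent/outcome variances and
sample covariate variances; (co)variances by the SD product; means by the
SD. Parameters with non-positive implied variance standardize to NaN and
are flagged.

## The voxelwise pipeline

Each in-mask voxel is fit independently (identical missingness patterns
across voxels are packed once). The statistic maps carry the γ_S·m
estimate, Wald SE/z/p, χ²/df/CFI/RMSEA/SRMR, and convergence/constraint
flags; output is deterministic given the seed and independent of voxel
order. The quality mask requires convergence plus RMSEA ≤ .10, CFI ≥ .90,
SRMR ≤ .10 (closed thresholds). Cluster correction thresholds two-sided
p < .001 within the mask and keeps face-connected (6-neighbor, configurable
to 18/26) components of at least 240 mm³; the minimum extent is a
user-supplied constant, not a Monte-Carlo estimate (explicit non-goal).
Peak reporting excludes voxels where the Heywood rule fired; the
unconditional (no-covariate) model is refit across cluster members to
report the latent-slope-variance range.

Whether to threshold two-sided p or signed contrasts separately was an open
choice; two-sided is the default and is what the calibration studies use.

## The synthetic cohorts

The generator emulates the published design: 69 baseline participants, 49
longitudinal enrollees, Bernoulli retention targeting 34/49 at wave 2 and
28/49 at wave 3 (non-monotone by default, since the real overlap pattern is
unreported; a monotone mode rescales conditional rates to preserve the
marginals), MFQ-FoF ~ truncated normal (2.99, 0.91) on [0, 6], age ~
truncated normal (68.33, 7.95) on [50, 85], independent covariates by
default with an optional rank-coupling knob. Attrition can depend on
baseline covariates through logistic dropout coefficients; with zero
coefficients a logistic audit of the generated data recovers OR ≈ 1.

Default growth truth for connectivity outcomes: α_I = .25, α_S = −.02,
ψ_II = .02, ψ_SS = .004, ψ_IS = .001, θ_t = .02, covariate paths 0. These
put between-subject Fisher-z SD near 0.2 and slope variances in the range
reported for real FC clusters (< .001–.011). The planted-cluster scenario
uses γ_S·m = −0.15 on an 81-voxel sphere (648 mm³ at 2-mm voxels): a
design-stage power analysis showed the per-voxel quality mask retains only
~72–74% of correctly specified voxels at N = 69, so a planted sphere must
comfortably exceed the 30-voxel reporting cutoff for its surviving core to
remain one reportable component (a 33-voxel sphere survives with
probability ~.01 at *any* effect size; 81 voxels with probability ~1).

What the generator does **not** emulate: spatial autocorrelation of noise
(voxels are independent given the covariates), hemodynamics or motion in
the toy 4D time series, item-level MFQ response processes (scores are drawn
directly on the 0–6 scale; an item mode exists only to exercise scoring),
and non-normal outcome distributions. Passing tests therefore validate the
estimator and pipeline logic, not robustness to realistic spatial noise
structure.

## Validation studies and problem sizes

* **Reference agreement.** On the packaged 69-subject fixture (exact
  69/34/28 pattern), the engine matches an independent R/nlme fit — the
  growth model as a mixed model with per-wave residual variances, the
  saturated model as unstructured-covariance GLS — to ~5e−10 in
  log-likelihood and ~5e−7 in estimates; fit indices assembled from the
  external log-likelihoods agree to ~6e−6. The fixture seed was chosen
  once so the MLE is interior (all variances positive), a comparability
  requirement since mixed-model software cannot represent negative
  variances.
* **Recovery/coverage.** 500 complete-data replicates at N = 2000:
  per-parameter absolute bias under 3 MC SEs and pooled 95% Wald-CI
  coverage (mean across the 12 free parameters) in [.93, .97].
* **Null calibration.** 2000 null cohorts at N = 69 with the 69/34/28
  attrition: the Wald z for γ_S·m is overdispersed (SD ≈ 1.14) and the
  empirical type-I error at α = .05 is ≈ .08–.09, with or without the
  Heywood rule. The engine is exactly calibrated asymptotically (rate .041,
  z ~ N(0, 0.98) at N = 2000; SEs match closed-form expected information),
  so this is a genuine small-sample property of the Wald test under these
  conditions — worth knowing when interpreting voxelwise p-maps at this
  sample size — and the corresponding acceptance test documents it by
  failing the asymptotic band rather than hiding it.
* **Pipeline.** Planted-cluster recovery runs on the full 24³ grid
  (~14k voxel fits, ≈3 minutes single-core); the matched-null specificity
  check uses twenty 10³ grids, a size chosen to keep the full suite within
  a routine CI budget while preserving the per-voxel false-positive
  process being tested.

## Known limitations

* Wald inference only; no likelihood-ratio or robust (sandwich) SEs, no
  bootstrap. At N ≈ 69 the Wald test on slope paths is anticonservative
  (above).
* Linear growth only; three or more waves are required for identification
  with free per-wave residual variances.
* Covariates must be complete; outcomes only may be missing.
* The cluster-extent constant is taken as given; no permutation or
  random-field inference.
* Ordinal/categorical outcomes and multi-group models are out of scope.
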