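# voxelgrowth

Latent growth modeling of longitudinal seed-based functional connectivity.

Subjective cognitive decline (SCD) — the self-perceived worsening of memory
with normal performance on formal testing — may mark a transition between
healthy aging and dementia. One way to study it is to ask whether the
*degree* of cognitive concern (the MFQ Frequency-of-Forgetting score,
rescaled to 0–6) predicts how resting-state functional connectivity (FC)
changes over several years. `voxelgrowth` implements that analysis as a
reusable, tested pipeline:

* **Seed maps.** 12-mm spherical seeds (posterior hippocampi, retrosplenial
  cortex, dorsal anterior insulae) on a gray-matter-masked grid; per
  subject and wave, the Fisher-z transformed Pearson correlation between
  the seed-mean BOLD series and every gray-matter voxel, with optional
  global-signal regression.
* **Per-voxel conditional latent growth models.** At every voxel, the FC
  values y₁..y_T follow

  y_it = η_I,i + λ_t η_S,i + ε_it,  with
  η_I,i = α_I + γ_I·m mᵢ + γ_I·a aᵢ + ζ_I,i and
  η_S,i = α_S + γ_S·m mᵢ + γ_S·a aᵢ + ζ_S,i,

  where m is baseline MFQ-FoF, a is baseline age centered at 70,
  λ = (0, 1, …, T−1) so the intercept is wave-1 status,
  Cov(ζ) = Ψ and Var(ε_it) = θ_t. Estimation is full-information maximum
  likelihood (FIML): each subject contributes the normal density of
  whatever waves they attended, valid under missing-at-random dropout.
* **Fit masking and cluster correction.** Voxels must satisfy RMSEA ≤ .10,
  CFI ≥ .90 and SRMR ≤ .10; the two-sided Wald p of γ_S·m is thresholded at
  p < .001 and surviving face-connected components must reach 240 mm³.
  Peak-voxel models (largest |γ̂_S·m| among constraint-free voxels) are
  reported per cluster, with unconditional-model slope-variance ranges.
* **Boundary handling.** Negative variance estimates whose 95% Wald CI
  covers 0 are fixed to 0 and the model refit (the Heywood rule), applied
  to residual variances and latent disturbances alike.
* **Parallel-process models.** A joint SEM couples the FC growth process to
  a cognitive-index growth process (S_cog ← I_fc, S_fc; all latents
  regressed on m and a), with delta-method indirect effects for
  mediation-style questions.
* **Synthetic cohorts.** A generator reproduces the study design — 69
  baseline participants, 49 longitudinal enrollees thinning to ~34 and ~28
  over three waves ~18 months apart, truncated-normal covariates, planted
  spatial effect clusters — so every stage is validated against known
  ground truth.

## Worked example

Fit the conditional growth model to the packaged 69-subject synthetic
fixture (three waves, 69/34/28 attendance):

```python
import pandas as pd
from voxelgrowth import LatentGrowthModel

tab = pd.read_csv("tests/data/fixture_cohort69.tsv", sep="\t")
model = LatentGrowthModel(covariates=("mfq_fof", "age_c"), seed=0)
model.fit(tab[["y1", "y2", "y3"]], tab[["mfq_fof", "age_c"]])

print(f"converged: {model.converged_}  (n = {len(tab)})")
for name in ("I~1", "S~1", "S~mfq_fof", "S~age_c", "I~~I", "S~~S"):
    print(f"  {name:10s} est = {model.params_[name]:+.4f}"
          f"  se = {model.se_[name]:.4f}  p = {model.pvalues_[name]:.3f}"
          f"  std = {model.std_[name]:+.3f}")
fi = model.fit_indices_
print(f"chi2({fi.df}) = {fi.chi2:.2f}, p = {fi.p:.2f}, CFI = {fi.cfi:.2f}, "
      f"RMSEA = {fi.rmsea:.3f} [{fi.rmsea_ci[0]:.2f}, {fi.rmsea_ci[1]:.2f}], "
      f"SRMR = {fi.srmr:.3f}")
```

which prints:

```
converged: True  (n = 69)
  I~1        est = +0.3076  se = 0.0854  p = 0.000  std = +2.058
  S~1        est = +0.0476  se = 0.0969  p = 0.623  std = +0.398
  S~mfq_fof  est = -0.0754  se = 0.0320  p = 0.018  std = -0.540
  S~age_c    est = +0.0000  se = 0.0036  p = 0.993  std = +0.002
  I~~I       est = +0.0197  se = 0.0160  p = 0.219  std = +0.881
  S~~S       est = +0.0101  se = 0.0102  p = 0.320  std = +0.708
chi2(3) = 5.26, p = 0.15, CFI = 0.88, RMSEA = 0.105 [0.00, 0.27], SRMR = 0.088
```

`S~mfq_fof` is the slope-on-concern path γ_S·m: here each MFQ-FoF point
predicts a −0.075 change in Fisher-z connectivity per measurement occasion
(standardized −0.54), while age is unrelated to change. The fit block is
the likelihood-ratio χ² against the FIML-saturated model with the usual
incremental (CFI), parsimony (RMSEA, with its noncentral-χ² 95% CI) and
residual (SRMR) indices. This fixture's fit (CFI .88, RMSEA .105) would
*fail* the pipeline's quality mask — voxels like it are excluded before
cluster correction.

The same model is available functionally (`voxelgrowth.fit_lgm`), and the
whole pipeline runs from the shell:

```bash
voxelgrowth simulate --out sim/ --grid 24 --cluster 12,12,12,2.6,-0.15 --seed 7
voxelgrowth fit-voxelwise --manifest sim/manifest.tsv \
    --covariates sim/covariates.tsv --out stats/ --seed 7
voxelgrowth clusters --pmap stats/stat-p.nii.gz \
    --fitmask stats/stat-converged.nii.gz --out clusters.tsv
```

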