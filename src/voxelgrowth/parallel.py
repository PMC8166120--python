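"""Parallel-process growth models linking connectivity change to cognitive
change.

Two linear growth processes — one over a voxel's Fisher-z connectivity
waves, one over a cognitive index (e.g. WMS-IV proportion scores) — are
fit jointly: the cognitive slope is regressed on the connectivity intercept
and slope, and every latent term is regressed on MFQ-FoF and centered age.
Indirect (mediation-style) effects of the covariate on cognitive change
through a connectivity growth term are estimated as path products with
delta-method standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .sem.fit import apply_heywood_rule, fit_sem
from .sem.likelihood import LongTable
from .sem.spec import Parameter, SemSpec, build_lgm_spec

__all__ = ["build_parallel_spec", "fit_parallel", "indirect_effect",
           "fit_cognitive_lgm", "IndirectEffect", "join_panels"]


def build_parallel_spec(fc_waves=3, cog_waves=3,
                        covariates=("mfq_fof", "age_c"), constraints=None,
                        fc_loadings=None, cog_loadings=None):
    """Joint spec of an FC growth block and a cognition growth block.

    Latents are ``I_fc, S_fc, I_cog, S_cog``; structural paths run
    ``S_cog <- I_fc`` and ``S_cog <- S_fc``; all four latents are regressed
    on each covariate; latent disturbances covary within blocks only.
    Optional ``constraints`` (e.g. ``{"S_cog~~S_cog": 0}``) reproduce
    boundary handling such as fixing a negative cognitive slope disturbance.
    """
    if fc_waves < 3 or cog_waves < 3:
        raise ValueError("need >= 3 waves per growth block")
    lam_fc = (np.arange(fc_waves, dtype=float) if fc_loadings is None
              else np.asarray(fc_loadings, float))
    lam_cog = (np.arange(cog_waves, dtype=float) if cog_loadings is None
               else np.asarray(cog_loadings, float))
    if lam_fc[0] != 0 or lam_cog[0] != 0:
        raise ValueError("first loading of each block must be 0")
    y_names = [f"fc{t + 1}" for t in range(fc_waves)] + \
              [f"cog{t + 1}" for t in range(cog_waves)]
    latents = ["I_fc", "S_fc", "I_cog", "S_cog"]
    T = fc_waves + cog_waves
    lam = np.zeros((T, 4))
    lam[:fc_waves, 0] = 1.0
    lam[:fc_waves, 1] = lam_fc
    lam[fc_waves:, 2] = 1.0
    lam[fc_waves:, 3] = lam_cog
    q = len(covariates)
    free = []
    for i, l in enumerate(latents):
        free.append(Parameter(f"{l}~1", "alpha", (i,), 0.0))
    free.append(Parameter("S_cog~I_fc", "B", (3, 0), 0.0))
    free.append(Parameter("S_cog~S_fc", "B", (3, 1), 0.0))
    for i, l in enumerate(latents):
        for j, x in enumerate(covariates):
            free.append(Parameter(f"{l}~{x}", "gamma", (i, j), 0.0))
    for i, l in enumerate(latents):
        free.append(Parameter(f"{l}~~{l}", "psi", (i, i), 1.0))
    free.append(Parameter("I_fc~~S_fc", "psi", (0, 1), 0.0))
    free.append(Parameter("I_cog~~S_cog", "psi", (2, 3), 0.0))
    for t, y in enumerate(y_names):
        free.append(Parameter(f"{y}~~{y}", "theta", (t,), 1.0))
    spec = SemSpec(y_names, list(covariates), latents, lam,
                   alpha=np.zeros(4), B=np.zeros((4, 4)),
                   gamma=np.zeros((4, q)), psi=np.zeros((4, 4)),
                   theta=np.zeros(T), free=free)
    if constraints:
        spec = spec.constrain(dict(constraints))
    spec.check_identified()
    return spec


def join_panels(fc_panel: LongTable, cog_panel: LongTable):
    """Align an FC panel and a cognition panel into one joint LongTable.

    Subjects must correspond row-by-row (identical covariate rows).
    """
    if fc_panel.n != cog_panel.n:
        raise ValueError("panels have different subject counts")
    if fc_panel.X.shape == cog_panel.X.shape and fc_panel.X.size:
        if not np.allclose(fc_panel.X, cog_panel.X):
            raise ValueError("panels disagree on covariate rows; subjects "
                             "are not aligned")
    Y = np.hstack([fc_panel.Y, cog_panel.Y])
    names = [f"fc{t + 1}" for t in range(fc_panel.n_waves)] + \
            [f"cog{t + 1}" for t in range(cog_panel.n_waves)]
    return LongTable(Y, fc_panel.X, y_names=names,
                     x_names=fc_panel.x_names)


def fit_parallel(spec, fc_panel, cog_panel=None, seed=0, n_starts=3,
                 heywood=True, **kwargs):
    """FIML fit of the parallel-process model.

    Accepts either a pre-joined LongTable (as ``fc_panel`` with
    ``cog_panel=None``) or the two block panels.  The Heywood
    constrain-and-refit rule applies to residual and latent disturbance
    variances alike.
    """
    data = fc_panel if cog_panel is None else join_panels(fc_panel, cog_panel)
    res = fit_sem(spec, data, seed=seed, n_starts=n_starts, **kwargs)
    if heywood and res.converged:
        res = apply_heywood_rule(res, spec, data, seed=seed,
                                 n_starts=n_starts, **kwargs)
    return res


@dataclass(frozen=True)
class IndirectEffect:
    """A two-path indirect effect a*b with a delta-method standard error."""

    label: str
    estimate: float
    se: float
    z: float
    p: float
    path_a: float
    path_b: float


def indirect_effect(fit, from_covariate, via_latent, to_latent="S_cog"):
    """Indirect effect of a covariate on ``to_latent`` through ``via_latent``.

    ``estimate = a * b`` where ``a`` is the ``via~covariate`` path and ``b``
    the ``to~via`` path; ``SE = sqrt(b^2 Var(a) + a^2 Var(b) + 2ab Cov(a,b))``.
    Raises if either component path is fixed/constrained out of the model.
    """
    name_a = f"{via_latent}~{from_covariate}"
    name_b = f"{to_latent}~{via_latent}"
    for nm in (name_a, name_b):
        if nm not in fit.estimates:
            raise ValueError(f"path {nm} is not a free parameter of this fit "
                             "(fixed or constrained)")
    if fit.vcov is None:
        raise ValueError("fit carries no parameter covariance; refit with "
                         "compute_se=True")
    a = fit.estimates[name_a]
    b = fit.estimates[name_b]
    ia = fit.spec.param_index(name_a)
    ib = fit.spec.param_index(name_b)
    va = fit.vcov[ia, ia]
    vb = fit.vcov[ib, ib]
    cab = fit.vcov[ia, ib]
    var = b * b * va + a * a * vb + 2.0 * a * b * cab
    se = float(np.sqrt(var)) if var > 0 else np.nan
    z = a * b / se if se and np.isfinite(se) and se > 0 else np.nan
    p = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
    return IndirectEffect(
        label=f"{from_covariate} -> {via_latent} -> {to_latent}",
        estimate=float(a * b), se=se, z=float(z) if np.isfinite(z) else np.nan,
        p=p, path_a=float(a), path_b=float(b))


def fit_cognitive_lgm(cog_panel, seed=0, n_starts=3, constraints=None,
                      **kwargs):
    """Conditional LGM for a cognitive index with boundary handling.

    Covariates are taken from the panel (MFQ-FoF and centered age by
    convention).  A negative latent-slope disturbance whose 95% CI covers 0
    is fixed to 0 and the model refit, mirroring the handling used for
    working-memory indices.
    """
    spec = build_lgm_spec(cog_panel.n_waves,
                          covariates=tuple(cog_panel.x_names),
                          constraints=constraints,
                          y_names=list(cog_panel.y_names))
    res = fit_sem(spec, cog_panel, seed=seed, n_starts=n_starts, **kwargs)
    if res.converged:
        res = apply_heywood_rule(res, spec, cog_panel, seed=seed,
                                 n_starts=n_starts, **kwargs)
    return res
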