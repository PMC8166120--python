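"""scikit-learn style estimators over the FIML growth-SEM engine.

These wrap the functional interface in fit/predict classes so growth models
compose with sklearn tooling (``get_params``/``set_params``, ``clone``).
The outcome panel plays the role of the data matrix: ``fit(Y, X)`` takes
the subjects-by-waves outcome matrix ``Y`` (NaN = missing wave) and the
complete covariate matrix ``X``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .parallel import build_parallel_spec
from .sem.fit import apply_heywood_rule, fit_sem
from .sem.likelihood import LongTable
from .sem.spec import build_lgm_spec

__all__ = ["LatentGrowthModel", "ParallelProcessModel"]


class _SemEstimator(BaseEstimator):
    def _finalize(self, spec, data):
        res = fit_sem(spec, data, n_starts=self.n_starts, seed=self.seed)
        if self.heywood and res.converged:
            res = apply_heywood_rule(res, spec, data, n_starts=self.n_starts,
                                     seed=self.seed)
        self.result_ = res
        self.spec_ = res.spec
        self.params_ = dict(res.estimates)
        self.se_ = dict(res.se)
        self.pvalues_ = dict(res.p)
        self.std_ = dict(res.std)
        self.loglik_ = res.loglik
        self.converged_ = res.converged
        self.constrained_params_ = list(res.constrained_params)
        self.fit_indices_ = res.fit
        self.n_features_in_ = data.X.shape[1]
        return self

    def score(self, Y, X=None):
        """Mean per-subject FIML log-likelihood under the fitted parameters."""
        data = self._table(Y, X)
        from .sem.likelihood import fiml_loglik
        params = np.array([self.params_.get(p.name, np.nan)
                           for p in self.spec_.free])
        return fiml_loglik(self.spec_, params, data) / data.n


class LatentGrowthModel(_SemEstimator):
    """Conditional linear latent growth model estimated by FIML.

    Parameters
    ----------
    loadings : sequence of float, optional
        Slope loadings (default 0, 1, ..., T-1; first must be 0 so the
        intercept is wave-1 status).
    covariates : sequence of str, optional
        Covariate names; defaults to ``x1..xq`` matching the columns of X.
    constraints : dict, optional
        Parameter name -> fixed value.
    heywood : bool
        Apply the negative-variance constrain-and-refit rule.
    n_starts, seed
        Deterministic jittered optimizer restarts.

    Attributes
    ----------
    params_, se_, pvalues_, std_ : dict
        Unstandardized/standardized solution keyed by tilde labels
        (``S~mfq_fof``, ``I~~S``, ``y1~~y1``, ``I~1``).
    fit_indices_ : FitIndices
        chi2/df/CFI/RMSEA (with 95% CI)/SRMR.
    converged_, constrained_params_, loglik_, result_
    """

    def __init__(self, loadings=None, covariates=None, constraints=None,
                 heywood=True, n_starts=3, seed=0):
        self.loadings = loadings
        self.covariates = covariates
        self.constraints = constraints
        self.heywood = heywood
        self.n_starts = n_starts
        self.seed = seed

    def _table(self, Y, X):
        Y = np.asarray(Y, float)
        names = (list(self.covariates) if self.covariates is not None
                 else None)
        return LongTable(Y, X, x_names=names)

    def fit(self, Y, X=None):
        data = self._table(Y, X)
        spec = build_lgm_spec(
            data.n_waves, loadings=self.loadings,
            covariates=tuple(data.x_names), constraints=self.constraints)
        return self._finalize(spec, data)

    def predict(self, X=None, n_waves=None):
        """Model-implied mean trajectory for covariate rows ``X``."""
        spec = self.spec_
        lam = spec.lam
        params = np.array([self.params_[p.name] for p in spec.free])
        alpha, B, gamma, psi, theta = spec.matrices(params)
        if X is None:
            X = np.zeros((1, spec.n_covariates))
        X = np.asarray(X, float).reshape(-1, spec.n_covariates)
        eta = alpha[None, :] + X @ gamma.T
        return eta @ lam.T


class ParallelProcessModel(_SemEstimator):
    """Joint growth model of connectivity and cognition with directed
    latent paths (``S_cog <- I_fc, S_fc``), FIML-estimated.

    ``fit(Y, X)`` expects the first ``fc_waves`` columns of Y to be the
    connectivity waves and the rest the cognitive-index waves.
    """

    def __init__(self, fc_waves=3, cog_waves=3, covariates=None,
                 constraints=None, heywood=True, n_starts=3, seed=0):
        self.fc_waves = fc_waves
        self.cog_waves = cog_waves
        self.covariates = covariates
        self.constraints = constraints
        self.heywood = heywood
        self.n_starts = n_starts
        self.seed = seed

    def _table(self, Y, X):
        Y = np.asarray(Y, float)
        if Y.shape[1] != self.fc_waves + self.cog_waves:
            raise ValueError(
                f"Y must have fc_waves + cog_waves = "
                f"{self.fc_waves + self.cog_waves} columns")
        names = (list(self.covariates) if self.covariates is not None
                 else [f"x{j+1}" for j in range((np.asarray(X).shape[1]
                                                 if X is not None else 0))])
        y_names = [f"fc{t+1}" for t in range(self.fc_waves)] + \
                  [f"cog{t+1}" for t in range(self.cog_waves)]
        return LongTable(Y, X, y_names=y_names, x_names=names)

    def fit(self, Y, X=None):
        data = self._table(Y, X)
        spec = build_parallel_spec(
            self.fc_waves, self.cog_waves, covariates=tuple(data.x_names),
            constraints=self.constraints)
        return self._finalize(spec, data)
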