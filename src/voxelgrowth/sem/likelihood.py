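"""Full-information maximum likelihood machinery for growth SEMs.

Each subject contributes the normal density of whatever outcomes they have
observed (covariates are required complete), which is valid under missing at
random.  Subjects are grouped by missingness pattern so the per-pattern
covariance factorizations are shared; the log-likelihood gradient is
analytic (chain rule through the structured mean and covariance), which is
what makes ~10^4 voxelwise fits per run feasible.  The pattern loops live in
:mod:`._kernels` (numba-compiled when available).
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from ._kernels import em_sweep, pattern_ll_grad

_LOG2PI = np.log(2.0 * np.pi)

__all__ = [
    "LongTable", "conditional_loglik", "covariate_loglik", "fiml_loglik",
    "implied_moments", "saturated_mvn_em", "saturated_loglik",
    "baseline_loglik", "complete_mvn_loglik",
]


def _pack_patterns(obs):
    """Sort rows by missingness pattern; return packed index structure."""
    n, T = obs.shape
    codes = obs @ (1 << np.arange(T))
    order = np.argsort(codes, kind="stable")
    uniq, counts = np.unique(codes[order], return_counts=True)
    ptr = np.zeros(len(uniq) + 1, np.int64)
    np.cumsum(counts, out=ptr[1:])
    obs_idx = np.zeros((len(uniq), T), np.int64)
    obs_len = np.zeros(len(uniq), np.int64)
    for p in range(len(uniq)):
        oidx = np.flatnonzero(obs[order[ptr[p]]])
        obs_len[p] = oidx.size
        obs_idx[p, :oidx.size] = oidx
    return order, ptr, obs_idx, obs_len


class LongTable:
    """Subjects x waves outcome matrix with missingness, plus covariates.

    Parameters
    ----------
    Y : ndarray, shape (n, T)
        Outcomes; ``NaN`` marks a missing wave.
    X : ndarray, shape (n, q)
        Complete exogenous covariates (may be empty, q = 0).
    y_names, x_names : sequences of str
    """

    def __init__(self, Y, X=None, y_names=None, x_names=None):
        Y = np.atleast_2d(np.asarray(Y, float))
        n, T = Y.shape
        if X is None:
            X = np.empty((n, 0))
        X = np.asarray(X, float).reshape(n, -1)
        if np.isnan(X).any():
            raise ValueError("covariates must be complete (no NaN)")
        obs = ~np.isnan(Y)
        if X.shape[1] == 0 and not obs.any(axis=1).all():
            raise ValueError("every subject needs >=1 observed outcome")
        self.Y = Y
        self.X = X
        self.y_names = list(y_names) if y_names is not None else [
            f"y{t + 1}" for t in range(T)]
        self.x_names = list(x_names) if x_names is not None else [
            f"x{j + 1}" for j in range(X.shape[1])]
        self.obs = obs
        # packed pattern structure over the outcomes (conditional likelihood)
        self.order, self.ptr, self.obs_idx, self.obs_len = _pack_patterns(obs)
        self.Ysort = np.ascontiguousarray(Y[self.order])
        self.Xsort = np.ascontiguousarray(X[self.order])
        # packed pattern structure over the joint (y, x) vector
        q = X.shape[1]
        jobs = np.hstack([obs, np.ones((n, q), bool)])
        self.jorder, self.jptr, self.jobs_idx, self.jobs_len = \
            _pack_patterns(jobs)
        self.Vsort = np.ascontiguousarray(
            np.hstack([Y, X])[self.jorder])
        self._x_stats = None

    @property
    def n(self):
        return self.Y.shape[0]

    @property
    def n_waves(self):
        return self.Y.shape[1]

    @property
    def patterns(self):
        """List of (observed wave indices, subject row indices) pairs."""
        out = []
        for p in range(self.obs_len.size):
            k = self.obs_len[p]
            if k:
                out.append((self.obs_idx[p, :k].copy(),
                            self.order[self.ptr[p]:self.ptr[p + 1]].copy()))
        return out

    @classmethod
    def from_frame(cls, frame, y_cols, x_cols=()):
        """Build from a wide-format pandas DataFrame."""
        Y = frame.loc[:, list(y_cols)].to_numpy(float)
        X = frame.loc[:, list(x_cols)].to_numpy(float) if len(x_cols) else None
        return cls(Y, X, y_names=list(y_cols), x_names=list(x_cols))

    def with_outcomes(self, Y):
        """Same subjects/covariates, new outcome matrix (voxelwise reuse)."""
        return LongTable(Y, self.X, self.y_names, self.x_names)

    def covariate_mle(self):
        """Sample MLE (mean, covariance with 1/n) of the covariate block."""
        if self._x_stats is None:
            q = self.X.shape[1]
            if q == 0:
                self._x_stats = (np.empty(0), np.empty((0, 0)))
            else:
                mu = self.X.mean(axis=0)
                R = self.X - mu
                self._x_stats = (mu, R.T @ R / self.n)
        return self._x_stats


def _structure(spec, params):
    alpha, B, gamma, psi, theta = spec.matrices(params)
    L = spec.n_latent
    A = np.linalg.inv(np.eye(L) - B) if np.any(B) else np.eye(L)
    LA = spec.lam @ A
    Sigma = LA @ psi @ LA.T + np.diag(theta)
    return alpha, B, gamma, psi, theta, A, LA, Sigma


def conditional_loglik(spec, params, data, grad=False):
    """log L(y | x) summed over subjects, optionally with its gradient.

    Returns ``ll`` or ``(ll, grad)``.  Non-positive-definite pattern
    submatrices yield ``-inf`` (with a zero gradient), which the optimizer
    treats as an infeasible step.
    """
    alpha, B, gamma, psi, theta, A, LA, Sigma = _structure(spec, params)
    X = data.Xsort
    U = alpha[:, None] + gamma @ X.T            # (L, n) sorted order
    M = np.ascontiguousarray(LA @ U)            # (T, n)
    ll, ok, W, G = pattern_ll_grad(
        data.Ysort, M, Sigma, data.ptr, data.obs_idx, data.obs_len,
        bool(grad))
    if not ok or not np.isfinite(ll):
        return (-np.inf, np.zeros(spec.n_free)) if grad else -np.inf
    if not grad:
        return ll
    g = np.empty(spec.n_free)
    AtLtG = LA.T @ G                            # (L, n)
    P = LA.T @ W @ LA                           # (L, L), symmetric
    plan = spec.plan()
    if "alpha" in plan:
        ks, idx = plan["alpha"]
        g[ks] = AtLtG.sum(axis=1)[idx[:, 0]]
    if "gamma" in plan:
        ks, idx = plan["gamma"]
        GX = AtLtG @ X                          # (L, q)
        g[ks] = GX[idx[:, 0], idx[:, 1]]
    if "psi" in plan:
        ks, idx = plan["psi"]
        w = np.where(idx[:, 0] == idx[:, 1], 1.0, 2.0)
        g[ks] = w * P[idx[:, 0], idx[:, 1]]
    if "theta" in plan:
        ks, idx = plan["theta"]
        g[ks] = np.diag(W)[idx[:, 0]]
    if "B" in plan:
        ks, idx = plan["B"]
        AU = A @ U
        dB = (A.T @ spec.lam.T @ G) @ AU.T \
            + 2.0 * LA.T @ W @ (LA @ psi @ A.T)
        g[ks] = dB[idx[:, 0], idx[:, 1]]
    return ll, g


def covariate_loglik(data, mu_x=None, Sigma_x=None):
    """Marginal normal log-likelihood of the covariate block.

    Defaults to the saturated MLE, where it is the constant shared by the
    fitted, saturated and baseline models (so it cancels from chi-square
    differences).
    """
    q = data.X.shape[1]
    if q == 0:
        return 0.0
    if mu_x is None or Sigma_x is None:
        mu_x, Sigma_x = data.covariate_mle()
    return complete_mvn_loglik(data.X, mu_x, Sigma_x)


def complete_mvn_loglik(V, mu, Sigma):
    """Multivariate normal log-likelihood of complete rows ``V``."""
    V = np.atleast_2d(V)
    n, p = V.shape
    if p == 0:
        return 0.0
    c, low = cho_factor(np.atleast_2d(Sigma), lower=True)
    R = (V - mu).T
    Z = cho_solve((c, low), R)
    logdet = 2.0 * np.log(np.diag(c)).sum()
    return -0.5 * (n * (p * _LOG2PI + logdet) + float(np.sum(R * Z)))


def fiml_loglik(spec, params, data, mu_x=None, Sigma_x=None):
    """Joint FIML log-likelihood over (y, x).

    The covariate block is saturated; unless explicit ``(mu_x, Sigma_x)``
    are supplied it is evaluated at its MLE.  With complete data this equals
    the standard multivariate-normal log-likelihood of the full vector.
    """
    return (conditional_loglik(spec, params, data)
            + covariate_loglik(data, mu_x, Sigma_x))


def implied_moments(spec, params, mu_x=None, Sigma_x=None, data=None):
    """Model-implied mean and covariance of the joint vector (y, x)."""
    if mu_x is None or Sigma_x is None:
        if data is not None:
            mu_x, Sigma_x = data.covariate_mle()
        else:
            q = spec.n_covariates
            mu_x, Sigma_x = np.zeros(q), np.eye(q)
    mu_x = np.asarray(mu_x, float)
    Sigma_x = np.asarray(Sigma_x, float).reshape(len(mu_x), len(mu_x))
    alpha, B, gamma, psi, theta, A, LA, _ = _structure(spec, params)
    mu_y = LA @ (alpha + gamma @ mu_x)
    Syy = LA @ (gamma @ Sigma_x @ gamma.T + psi) @ LA.T + np.diag(theta)
    Syx = LA @ gamma @ Sigma_x
    mu = np.concatenate([mu_y, mu_x])
    Sigma = np.block([[Syy, Syx], [Syx.T, Sigma_x]])
    return mu, Sigma


def _joint_loglik_unstructured(data, mu, Sigma):
    ll, ok, _, _ = pattern_ll_grad(
        data.Vsort, np.repeat(mu[:, None], data.n, axis=1), Sigma,
        data.jptr, data.jobs_idx, data.jobs_len, False)
    return ll if ok else -np.inf


def saturated_mvn_em(data, tol=1e-10, max_iter=2000):
    """Unstructured-(mu, Sigma) FIML MLE of the joint (y, x) vector by EM.

    Returns ``(mu, Sigma, loglik, n_iter)``.  Raises if any variable is
    never observed (its moments are inestimable).
    """
    if not data.obs.any(axis=0).all():
        bad = [data.y_names[t] for t in np.flatnonzero(~data.obs.any(axis=0))]
        raise ValueError(f"variable(s) never observed: {bad}")
    V = data.Vsort
    n, p = V.shape
    mu, Sigma = _available_case_moments(V)
    ll_old = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        ll, ok, sum_v, sum_vv = em_sweep(
            V, mu, Sigma, data.jptr, data.jobs_idx, data.jobs_len)
        if not ok:
            Sigma = Sigma + 1e-8 * np.trace(Sigma) / p * np.eye(p)
            continue
        mu = sum_v / n
        Sigma = sum_vv / n - np.outer(mu, mu)
        Sigma = 0.5 * (Sigma + Sigma.T)
        if ll - ll_old < tol * (1.0 + abs(ll)) and it > 1:
            break
        ll_old = ll
    ll = _joint_loglik_unstructured(data, mu, Sigma)
    return mu, Sigma, ll, it


def _available_case_moments(V):
    """Pairwise-complete moment estimates, ridged to positive definite."""
    n, p = V.shape
    mu = np.nanmean(V, axis=0)
    Vc = V - mu
    Sigma = np.zeros((p, p))
    for i in range(p):
        for j in range(i, p):
            both = ~np.isnan(Vc[:, i]) & ~np.isnan(Vc[:, j])
            v = float(np.mean(Vc[both, i] * Vc[both, j])) if both.any() else 0.0
            Sigma[i, j] = Sigma[j, i] = v
    w = np.linalg.eigvalsh(Sigma)
    scale = max(w.max(), 1e-8)
    if w.min() < 1e-8 * scale:
        Sigma += (1e-8 * scale - min(w.min(), 0.0)) * np.eye(p)
    return mu, Sigma


def saturated_loglik(data, **kwargs):
    """FIML log-likelihood at the unstructured mean/covariance MLE (via EM)."""
    return saturated_mvn_em(data, **kwargs)[2]


def baseline_loglik(data):
    """Independence-baseline model log-likelihood (for CFI).

    Outcomes get free means and variances with all covariances fixed to 0,
    so the FIML likelihood separates per outcome and each piece is maximized
    by the observed-case mean and (1/n) variance.  The exogenous covariate
    block stays saturated, as in the fitted model, so it cancels from CFI.
    Returns ``(loglik, n_free_total)``.
    """
    ll = 0.0
    for t in range(data.n_waves):
        y = data.Y[:, t]
        y = y[~np.isnan(y)]
        if y.size == 0:
            raise ValueError(f"outcome {data.y_names[t]} never observed")
        v = float(np.var(y))
        if v <= 0:
            raise ValueError(f"outcome {data.y_names[t]} has zero variance")
        ll += -0.5 * y.size * (_LOG2PI + np.log(v) + 1.0)
    ll += covariate_loglik(data)
    q = data.X.shape[1]
    k = 2 * data.n_waves + q * (q + 3) // 2
    return ll, k
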