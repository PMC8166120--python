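"""Maximum-likelihood fitting of growth SEMs, fit indices, Heywood handling.

Estimation maximizes the pattern-grouped FIML log-likelihood by BFGS with
the analytic gradient, from a moment-based start plus deterministic jittered
restarts.  Variance parameters are deliberately left unconstrained so that
negative (Heywood) estimates are observable and can be handled by the
constrain-to-zero-and-refit rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .likelihood import (LongTable, baseline_loglik, conditional_loglik,
                         covariate_loglik, implied_moments, saturated_mvn_em)
from .spec import SemSpec

__all__ = ["FitIndices", "FitResult", "fit_sem", "fit_lgm", "fit_indices",
           "standardize", "apply_heywood_rule", "rmsea_ci", "srmr"]


@dataclass
class FitIndices:
    chi2: float
    df: int
    p: float
    cfi: float
    rmsea: float
    rmsea_ci: tuple
    srmr: float
    chi2_baseline: float = np.nan
    df_baseline: int = 0

    def to_dict(self):
        return {"chi2": self.chi2, "df": self.df, "p": self.p,
                "cfi": self.cfi, "rmsea": self.rmsea,
                "rmsea_ci_lower": self.rmsea_ci[0],
                "rmsea_ci_upper": self.rmsea_ci[1], "srmr": self.srmr}


@dataclass
class FitResult:
    """Estimates and diagnostics from one SEM fit."""

    spec: SemSpec
    estimates: dict
    se: dict
    z: dict
    p: dict
    std: dict
    loglik: float                 # joint (y, x) log-likelihood
    loglik_cond: float            # conditional-on-covariates part
    n_used: int
    converged: bool
    n_iter: int = 0
    fit: FitIndices | None = None
    constrained_params: list = field(default_factory=list)
    inadmissible: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    vcov: np.ndarray | None = None

    @property
    def param_names(self):
        return list(self.estimates)

    def to_dict(self):
        out = {
            "n": self.n_used, "loglik": self.loglik,
            "converged": bool(self.converged),
            "constrained": list(self.constrained_params),
            "inadmissible": list(self.inadmissible),
            "warnings": list(self.warnings),
            "parameters": [
                {"label": k, "estimate": self.estimates[k],
                 "se": self.se.get(k, np.nan), "z": self.z.get(k, np.nan),
                 "p": self.p.get(k, np.nan), "std": self.std.get(k, np.nan)}
                for k in self.estimates],
        }
        if self.fit is not None:
            out["fit"] = self.fit.to_dict()
        return out


# ---------------------------------------------------------------------------
# starting values

def _start_values(spec, data, moments=None):
    """Moment-based starting values.

    Uses the saturated-EM joint moments when available (close to the MLE,
    so quasi-Newton converges in few steps); otherwise available-case
    moments.
    """
    T, q = spec.n_waves, spec.n_covariates
    if moments is not None:
        mu, S = moments
        S = S + 0.0
    else:
        V = np.hstack([data.Y, data.X])
        mu = np.nanmean(V, axis=0)
        Vc = V - mu
        p = T + q
        S = np.zeros((p, p))
        for i in range(p):
            for j in range(i, p):
                both = ~np.isnan(Vc[:, i]) & ~np.isnan(Vc[:, j])
                S[i, j] = S[j, i] = (float(np.mean(Vc[both, i] * Vc[both, j]))
                                     if both.any() else 0.0)
    Syy = S[:T, :T]
    if q:
        Sxx = S[T:, T:] + 1e-10 * np.eye(q)
        C = np.linalg.solve(Sxx, S[T:, :T]).T         # (T, q) regression
        c0 = mu[:T] - C @ mu[T:]
        Sres = Syy - C @ Sxx @ C.T
    else:
        C = np.zeros((T, 0))
        c0 = mu[:T]
        Sres = Syy
    lam_pinv = np.linalg.pinv(spec.lam)
    psi0, theta0 = _decompose_residual(spec.lam, Sres)
    alpha0 = lam_pinv @ c0
    gamma0 = lam_pinv @ C
    start = np.empty(spec.n_free)
    for k, prm in enumerate(spec.free):
        if prm.matrix == "alpha":
            start[k] = alpha0[prm.index[0]] if prm.index[0] < len(alpha0) else 0.0
        elif prm.matrix == "gamma":
            start[k] = gamma0[prm.index]
        elif prm.matrix == "psi":
            start[k] = psi0[prm.index]
        elif prm.matrix == "theta":
            start[k] = theta0[prm.index[0]]
        else:                                          # B paths
            start[k] = 0.0
    return start


def _decompose_residual(lam, Sres):
    """Method-of-moments split of a residual covariance into lam Psi lam'
    + diag(theta), via least squares on the off-diagonal entries.

    For a 3-wave linear growth model this solve is exact, which puts the
    quasi-Newton start essentially at the MLE.
    """
    T, L = lam.shape
    pairs = [(i, j) for i in range(T) for j in range(i + 1, T)]
    cols = [(a, b) for a in range(L) for b in range(a, L)]
    if pairs and cols:
        A = np.empty((len(pairs), len(cols)))
        for r, (i, j) in enumerate(pairs):
            for c, (a, b) in enumerate(cols):
                v = lam[i, a] * lam[j, b]
                if a != b:
                    v += lam[i, b] * lam[j, a]
                A[r, c] = v
        rhs = np.array([Sres[i, j] for i, j in pairs])
        sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
        psi0 = np.zeros((L, L))
        for c, (a, b) in enumerate(cols):
            psi0[a, b] = psi0[b, a] = sol[c]
    else:
        psi0 = np.zeros((L, L))
    scale = max(np.diag(Sres).max(), 1e-8)
    w, Q = np.linalg.eigh(psi0)
    psi0 = Q @ np.diag(np.maximum(w, 1e-3 * scale)) @ Q.T
    theta0 = np.maximum(np.diag(Sres - lam @ psi0 @ lam.T), 1e-3 * scale)
    return psi0, theta0


# ---------------------------------------------------------------------------
# core fit

def fit_sem(spec, data, n_starts=3, seed=0, compute_se=True,
            compute_fit_indices=True, rmsea_interval=True, gtol=1e-6,
            start=None):
    """Fit a :class:`SemSpec` to a :class:`LongTable` by FIML.

    Returns a :class:`FitResult`.  ``n_starts`` deterministic jittered starts
    (seeded by ``seed``) guard against local optima; the best optimum is kept.
    """
    spec.check_identified()
    if data.X.shape[1] != spec.n_covariates:
        raise ValueError(
            f"data has {data.X.shape[1]} covariates but the model expects "
            f"{spec.n_covariates}")
    nf = spec.n_free

    def objective(th):
        ll, g = conditional_loglik(spec, th, data, grad=True)
        if not np.isfinite(ll):
            return 1e12, np.zeros(nf)
        return -ll, -g

    sat_moments = None
    if compute_fit_indices:
        # the saturated moments are needed for the fit block anyway and
        # give near-MLE starting values
        try:
            mu_sat, S_sat, ll_sat, _ = saturated_mvn_em(data)
            sat_moments = (mu_sat, S_sat, ll_sat)
        except (ValueError, np.linalg.LinAlgError):
            sat_moments = None
    if start is not None:
        base = np.asarray(start, float)
    else:
        base = _start_values(
            spec, data,
            moments=sat_moments[:2] if sat_moments is not None else None)
    rng = np.random.default_rng(seed)
    scale = np.maximum(np.abs(base), 0.05)
    best = None       # (fun, x, jac, hess_or_None)
    n_iter = 0
    for s in range(max(1, n_starts)):
        x0 = base if s == 0 else base + 0.25 * scale * rng.standard_normal(nf)
        # damped Newton from the moment start (usually a handful of steps);
        # quasi-Newton fallback when it stalls
        sol = _newton_polish(spec, x0, data, gtol=gtol)
        if sol is None:
            res = optimize.minimize(objective, x0, jac=True, method="BFGS",
                                    options={"gtol": gtol, "maxiter": 500})
            sol = (res.fun, res.x, res.jac, None, res.nit)
        n_iter += sol[4]
        if np.isfinite(sol[0]) and (best is None or sol[0] < best[0] - 1e-10):
            best = sol
    if best is None:
        return FitResult(spec, {}, {}, {}, {}, {}, -np.inf, -np.inf, data.n,
                         False, n_iter, warnings=["all starts failed"])
    # gradient criterion is relative to the log-likelihood scale, so large-N
    # fits are not spuriously rejected
    fun, est, jac, hess, _ = best
    converged = np.isfinite(fun) and (
        np.linalg.norm(jac, np.inf) < 1e-5 * max(1.0, abs(fun)))
    ll_cond = -fun
    ll_joint = ll_cond + covariate_loglik(data)
    names = spec.param_names
    estimates = dict(zip(names, est))
    se = {}
    zv = {}
    pv = {}
    vcov = None
    if compute_se and converged:
        H = _numeric_hessian(spec, est, data)
        vcov = _safe_inverse(H)
        d = np.diag(vcov).copy()
        bad = d < 0
        d[bad] = np.nan
        ses = np.sqrt(d)
        se = dict(zip(names, ses))
        with np.errstate(invalid="ignore", divide="ignore"):
            zs = est / ses
        zv = dict(zip(names, zs))
        pv = dict(zip(names, 2.0 * stats.norm.sf(np.abs(zs))))
    result = FitResult(spec, estimates, se, zv, pv, {}, ll_joint, ll_cond,
                       data.n, bool(converged), n_iter, vcov=vcov)
    if converged:
        result.std = standardize(result, spec, data)
        if compute_fit_indices:
            result.fit = _indices_for_fit(result, spec, data,
                                          rmsea_interval=rmsea_interval,
                                          sat=sat_moments)
    return result


def _newton_polish(spec, x0, data, gtol=1e-6, max_iter=60):
    """Quasi-Newton minimization of -loglik seeded with the true Hessian.

    One observed-information evaluation at the moment-based start provides
    the initial curvature (the start is near the MLE for growth structures,
    so the surface is badly scaled but locally quadratic); subsequent
    iterations use inverse-BFGS rank-2 updates with Armijo backtracking.
    Returns ``(f, x, grad, None, n_iter)`` or None to signal the generic
    BFGS fallback.
    """
    x = np.asarray(x0, float).copy()
    ll, g = conditional_loglik(spec, x, data, grad=True)
    if not np.isfinite(ll):
        return None
    f, g = -ll, -g
    nf = x.size
    Hinv = None
    refreshes = 0
    for it in range(1, max_iter + 1):
        if np.linalg.norm(g, np.inf) < 1e-7 * max(1.0, abs(f)):
            return f, x, g, None, it
        if Hinv is None:
            H = _numeric_hessian(spec, x, data)
            ridge = 0.0
            for _ in range(8):
                try:
                    c = np.linalg.cholesky(H + ridge * np.eye(nf))
                    break
                except np.linalg.LinAlgError:
                    ridge = max(2.0 * ridge, 1e-6 * max(np.trace(H), 1.0))
            else:
                return None
            ci = np.linalg.inv(c)
            Hinv = ci.T @ ci
        step = -Hinv @ g
        slope = g @ step
        if slope >= 0:
            if refreshes < 1:
                Hinv, refreshes = None, refreshes + 1
                continue
            return None
        t = 1.0
        accepted = False
        for _ in range(25):
            xn = x + t * step
            lln, gn = conditional_loglik(spec, xn, data, grad=True)
            if np.isfinite(lln) and -lln <= f + 1e-4 * t * slope:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            if refreshes < 1:
                Hinv, refreshes = None, refreshes + 1
                continue
            return None
        s = t * step
        y = -gn - g
        sy = s @ y
        if sy > 1e-12 * np.linalg.norm(s) * np.linalg.norm(y):
            Hy = Hinv @ y
            rho = 1.0 / sy
            Hinv = (Hinv - rho * (np.outer(s, Hy) + np.outer(Hy, s))
                    + rho * (1.0 + rho * (y @ Hy)) * np.outer(s, s))
        x, f, g = xn, -lln, -gn
    return None


def fit_lgm(spec, data, n_starts=3, seed=0, **kwargs):
    """Fit a latent growth model (thin alias of :func:`fit_sem`)."""
    return fit_sem(spec, data, n_starts=n_starts, seed=seed, **kwargs)


def _numeric_hessian(spec, est, data, rel_step=1e-5):
    """Observed information via central differences of the analytic gradient."""
    nf = est.size
    H = np.zeros((nf, nf))
    for k in range(nf):
        h = rel_step * max(1.0, abs(est[k]))
        ep = est.copy()
        em = est.copy()
        ep[k] += h
        em[k] -= h
        _, gp = conditional_loglik(spec, ep, data, grad=True)
        _, gm = conditional_loglik(spec, em, data, grad=True)
        H[k] = -(gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


def _safe_inverse(H):
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H)


# ---------------------------------------------------------------------------
# fit indices

def fit_indices(logL_model, k_model, logL_sat, logL_baseline, k_baseline, N,
                n_moments, srmr_value=np.nan, use_n_minus_1=False,
                rmsea_interval=True):
    """Likelihood-ratio chi-square and the CFI/RMSEA/SRMR block.

    ``chi2 = 2 (logL_sat - logL_model)`` with ``df = moments - free``;
    CFI compares against the independence baseline; RMSEA uses the
    ``sqrt(max(chi2 - df, 0) / (df * N))`` form with a noncentral-chi-square
    95% interval.  When ``chi2 <= df`` RMSEA is 0 by construction.
    """
    df = n_moments - k_model
    df_b = n_moments - k_baseline
    chi2 = max(2.0 * (logL_sat - logL_model), 0.0)
    chi2_b = max(2.0 * (logL_sat - logL_baseline), 0.0)
    Neff = N - 1 if use_n_minus_1 else N
    if df <= 0:
        return FitIndices(chi2=chi2, df=max(df, 0), p=1.0, cfi=1.0, rmsea=0.0,
                          rmsea_ci=(0.0, 0.0), srmr=srmr_value,
                          chi2_baseline=chi2_b, df_baseline=df_b)
    p = float(stats.chi2.sf(chi2, df))
    d_m = max(chi2 - df, 0.0)
    d_b = max(chi2_b - df_b, 0.0)
    cfi = 1.0 if max(d_m, d_b) == 0 else 1.0 - d_m / max(d_m, d_b)
    rmsea = float(np.sqrt(d_m / (df * Neff)))
    ci = rmsea_ci(chi2, df, Neff) if rmsea_interval else (np.nan, np.nan)
    return FitIndices(chi2=chi2, df=df, p=p, cfi=float(np.clip(cfi, 0, 1)),
                      rmsea=rmsea, rmsea_ci=ci, srmr=srmr_value,
                      chi2_baseline=chi2_b, df_baseline=df_b)


def rmsea_ci(chi2, df, N, level=0.95):
    """Noncentral-chi-square confidence interval for RMSEA (root finding)."""
    lo_p = 0.5 + level / 2.0
    hi_p = 0.5 - level / 2.0

    def ncp_for(prob):
        # find lambda with P(X2_{df,lambda} <= chi2) = prob; the cdf
        # underflows to NaN at extreme noncentrality, where it is ~0
        def f(lam):
            v = stats.ncx2.cdf(chi2, df, lam)
            return (v if np.isfinite(v) else 0.0) - prob
        if f(0.0) < 0:
            return 0.0
        hi = max(chi2, 1.0)
        while f(hi) > 0 and hi < 1e8:
            hi *= 2.0
        if f(hi) > 0:
            return hi
        return optimize.brentq(f, 0.0, hi, xtol=1e-10)

    lam_lo = ncp_for(lo_p)
    lam_hi = ncp_for(hi_p)
    return (float(np.sqrt(lam_lo / (df * N))), float(np.sqrt(lam_hi / (df * N))))


def srmr(S_sat, Sigma_model, include_means=False, mu_sat=None, mu_model=None):
    """Standardized root-mean-square residual over covariance entries.

    Residuals between the saturated-estimate and model-implied covariances,
    standardized by the saturated SDs; lower-triangle (including diagonal)
    entries are averaged.  Mean residuals are excluded by default.
    """
    S_sat = np.asarray(S_sat, float)
    Sigma_model = np.asarray(Sigma_model, float)
    sd = np.sqrt(np.diag(S_sat))
    denom = np.outer(sd, sd)
    Rm = (S_sat - Sigma_model) / denom
    idx = np.tril_indices_from(Rm)
    terms = list(Rm[idx] ** 2)
    if include_means and mu_sat is not None:
        terms += list(((np.asarray(mu_sat) - np.asarray(mu_model)) / sd) ** 2)
    return float(np.sqrt(np.mean(terms)))


def _indices_for_fit(result, spec, data, rmsea_interval=True, sat=None):
    if sat is not None:
        mu_sat, S_sat, ll_sat = sat
    else:
        mu_sat, S_sat, ll_sat, _ = saturated_mvn_em(data)
    ll_base, k_base = baseline_loglik(data)
    mu_m, Sigma_m = implied_moments(spec, np.array(
        [result.estimates[n] for n in spec.param_names]), data=data)
    s = srmr(S_sat, Sigma_m)
    return fit_indices(result.loglik, spec.n_free_total(), ll_sat,
                       ll_base, k_base, data.n, spec.n_moments(),
                       srmr_value=s, rmsea_interval=rmsea_interval)


# ---------------------------------------------------------------------------
# standardization

def standardize(result, spec, data):
    """std.all standardized solution from model-implied variances.

    Each path is scaled by SD(predictor)/SD(outcome); (co)variances by the
    product of the two SDs; means by the variable SD.  Exogenous covariates
    use their sample SDs.  Parameters whose implied variance is not positive
    are returned as NaN (flagged undefined).
    """
    params = np.array([result.estimates[n] for n in spec.param_names])
    alpha, B, gamma, psi, theta = spec.matrices(params)
    L = spec.n_latent
    A = np.linalg.inv(np.eye(L) - B) if np.any(B) else np.eye(L)
    mu_x, Sigma_x = data.covariate_mle()
    V_eta = A @ (gamma @ Sigma_x @ gamma.T + psi) @ A.T
    var_eta = np.diag(V_eta)
    var_y = np.diag(spec.lam @ V_eta @ spec.lam.T) + theta
    var_x = np.diag(Sigma_x) if Sigma_x.size else np.empty(0)

    def sd(v):
        return np.sqrt(v) if v > 0 else np.nan

    sd_eta = np.array([sd(v) for v in var_eta])
    sd_y = np.array([sd(v) for v in var_y])
    sd_x = np.array([sd(v) for v in var_x])
    std = {}
    for k, prm in enumerate(spec.free):
        v = params[k]
        if prm.matrix == "alpha":
            std[prm.name] = v / sd_eta[prm.index[0]]
        elif prm.matrix == "gamma":
            i, j = prm.index
            std[prm.name] = v * sd_x[j] / sd_eta[i]
        elif prm.matrix == "B":
            i, j = prm.index
            std[prm.name] = v * sd_eta[j] / sd_eta[i]
        elif prm.matrix == "psi":
            i, j = prm.index
            std[prm.name] = v / (sd_eta[i] * sd_eta[j])
        elif prm.matrix == "theta":
            t = prm.index[0]
            std[prm.name] = v / var_y[t] if var_y[t] > 0 else np.nan
    return std


# ---------------------------------------------------------------------------
# Heywood (negative variance) constrain-and-refit rule

def _variance_params(spec):
    out = []
    for p in spec.free:
        if p.matrix == "theta":
            out.append(p.name)
        elif p.matrix == "psi" and p.index[0] == p.index[1]:
            out.append(p.name)
    return out


def apply_heywood_rule(result, spec, data, z_crit=1.959963984540054,
                       n_starts=3, seed=0, **fit_kwargs):
    """Constrain negative variance estimates to 0 and refit.

    A negative residual or latent-disturbance variance whose 95% Wald
    interval covers 0 is treated as sampling error at the boundary: it is
    fixed to 0 (together with any covariance involving a zeroed latent
    disturbance, to keep Psi admissible) and the model is refit, iterating
    until no new violation appears.  A negative variance whose interval
    excludes 0 is flagged inadmissible and left alone.
    """
    if not result.converged:
        return result
    constrained = list(result.constrained_params)
    inadmissible = []
    current = result
    cur_spec = spec
    for _ in range(len(_variance_params(spec)) + 1):
        to_fix = {}
        for name in _variance_params(cur_spec):
            est = current.estimates.get(name, np.nan)
            s = current.se.get(name, np.nan)
            if est < 0:
                if not np.isfinite(s) or est + z_crit * s >= 0:
                    to_fix[name] = 0.0
                elif name not in inadmissible:
                    inadmissible.append(name)
        if not to_fix:
            break
        # zero any free covariance attached to a zeroed latent variance
        for name in list(to_fix):
            for p in cur_spec.free:
                if p.matrix == "psi" and p.index[0] != p.index[1]:
                    a, b = p.index
                    la = cur_spec.latent_names[a]
                    lb = cur_spec.latent_names[b]
                    if name in (f"{la}~~{la}", f"{lb}~~{lb}"):
                        to_fix.setdefault(p.name, 0.0)
        new_spec = cur_spec.constrain(to_fix)
        # intermediate refits only need estimates and SEs; the final fit
        # block is recomputed once below
        kw = dict(fit_kwargs)
        kw["compute_fit_indices"] = False
        kw.pop("rmsea_interval", None)
        warm = np.array([current.estimates[p.name] for p in new_spec.free])
        refit = fit_sem(new_spec, data, n_starts=n_starts, seed=seed,
                        start=warm, **kw)
        if not refit.converged:
            result.warnings.append(
                f"refit after constraining {sorted(to_fix)} failed to "
                "converge; returning unconstrained fit")
            result.inadmissible = inadmissible
            return result
        constrained.extend(sorted(to_fix))
        current = refit
        cur_spec = new_spec
    current.constrained_params = constrained
    current.inadmissible = inadmissible
    if (constrained and current.fit is None
            and fit_kwargs.get("compute_fit_indices", True)):
        current.fit = _indices_for_fit(
            current, cur_spec, data,
            rmsea_interval=fit_kwargs.get("rmsea_interval", True))
    return current
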