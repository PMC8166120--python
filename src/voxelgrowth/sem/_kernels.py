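"""Hot numerical kernels for the FIML engine.

The voxelwise driver runs tens of thousands of small fits, so the
pattern-grouped log-likelihood/gradient and the EM sweep are JIT-compiled
with numba when available; the module falls back to equivalent numpy code
otherwise.  All matrices here are tiny (order of the number of waves), so
Cholesky factorization and the triangular solves are written out explicitly.
"""

from __future__ import annotations

import numpy as np

_LOG2PI = np.log(2.0 * np.pi)

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=False)
def _chol(S, L):
    """In-place lower Cholesky of S into L; returns False if not PD."""
    k = S.shape[0]
    for i in range(k):
        for j in range(i + 1):
            acc = S[i, j]
            for t in range(j):
                acc -= L[i, t] * L[j, t]
            if i == j:
                if acc <= 0.0:
                    return False
                L[i, i] = np.sqrt(acc)
            else:
                L[i, j] = acc / L[j, j]
    return True


@njit(cache=False)
def _solve_chol(L, B, Z):
    """Solve (L L') Z = B for Z, shapes (k,k),(k,m)."""
    k, m = B.shape
    for c in range(m):
        for i in range(k):
            acc = B[i, c]
            for t in range(i):
                acc -= L[i, t] * Z[t, c]
            Z[i, c] = acc / L[i, i]
        for i in range(k - 1, -1, -1):
            acc = Z[i, c]
            for t in range(i + 1, k):
                acc -= L[t, i] * Z[t, c]
            Z[i, c] = acc / L[i, i]


@njit(cache=False)
def pattern_ll_grad(Ysort, M, Sigma, ptr, obs_idx, obs_len, want_grad):
    """Pattern-grouped normal log-likelihood with mean/covariance gradients.

    Ysort : (n, T) outcomes sorted by missingness pattern (NaN = missing)
    M     : (T, n) per-subject model means, same order
    Sigma : (T, T) common model covariance
    ptr   : (P+1,) row boundaries per pattern
    obs_idx, obs_len : (P, T), (P,) observed wave indices per pattern

    Returns (ll, ok, W, G) with W = dll/dSigma (T, T) and G = dll/dmean
    (T, n); W and G are zero when ``want_grad`` is False or on failure.
    """
    T = Sigma.shape[0]
    n = Ysort.shape[0]
    P = obs_len.shape[0]
    W = np.zeros((T, T))
    G = np.zeros((T, n))
    ll = 0.0
    for p in range(P):
        k = obs_len[p]
        r0, r1 = ptr[p], ptr[p + 1]
        m = r1 - r0
        if k == 0 or m == 0:
            continue
        S = np.empty((k, k))
        for i in range(k):
            for j in range(k):
                S[i, j] = Sigma[obs_idx[p, i], obs_idx[p, j]]
        L = np.zeros((k, k))
        if not _chol(S, L):
            return -np.inf, False, W, G
        logdet = 0.0
        for i in range(k):
            logdet += 2.0 * np.log(L[i, i])
        R = np.empty((k, m))
        for c in range(m):
            row = r0 + c
            for i in range(k):
                o = obs_idx[p, i]
                R[i, c] = Ysort[row, o] - M[o, row]
        Z = np.empty((k, m))
        _solve_chol(L, R, Z)
        quad = 0.0
        for i in range(k):
            for c in range(m):
                quad += R[i, c] * Z[i, c]
        ll += -0.5 * (m * (k * _LOG2PI + logdet) + quad)
        if want_grad:
            for c in range(m):
                row = r0 + c
                for i in range(k):
                    G[obs_idx[p, i], row] = Z[i, c]
            Eye = np.eye(k)
            Sinv = np.empty((k, k))
            _solve_chol(L, Eye, Sinv)
            for i in range(k):
                oi = obs_idx[p, i]
                for j in range(k):
                    oj = obs_idx[p, j]
                    zz = 0.0
                    for c in range(m):
                        zz += Z[i, c] * Z[j, c]
                    W[oi, oj] += 0.5 * (zz - m * Sinv[i, j])
    return ll, True, W, G


@njit(cache=False)
def em_sweep(Vsort, mu, Sigma, ptr, obs_idx, obs_len):
    """One EM E-step for unstructured-MVN missing data.

    Returns (ll, ok, sum_v, sum_vv) where the sums are expected complete-data
    sufficient statistics under the current (mu, Sigma).
    """
    n, p = Vsort.shape
    P = obs_len.shape[0]
    sum_v = np.zeros(p)
    sum_vv = np.zeros((p, p))
    ll = 0.0
    for pi in range(P):
        k = obs_len[pi]
        r0, r1 = ptr[pi], ptr[pi + 1]
        m = r1 - r0
        if m == 0 or k == 0:
            continue
        # observed / missing index split
        is_obs = np.zeros(p, np.bool_)
        for i in range(k):
            is_obs[obs_idx[pi, i]] = True
        nmis = p - k
        mis = np.empty(nmis, np.int64)
        t = 0
        for j in range(p):
            if not is_obs[j]:
                mis[t] = j
                t += 1
        S = np.empty((k, k))
        for i in range(k):
            for j in range(k):
                S[i, j] = Sigma[obs_idx[pi, i], obs_idx[pi, j]]
        L = np.zeros((k, k))
        if not _chol(S, L):
            return -np.inf, False, sum_v, sum_vv
        logdet = 0.0
        for i in range(k):
            logdet += 2.0 * np.log(L[i, i])
        R = np.empty((k, m))
        for c in range(m):
            row = r0 + c
            for i in range(k):
                R[i, c] = Vsort[row, obs_idx[pi, i]] - mu[obs_idx[pi, i]]
        Z = np.empty((k, m))
        _solve_chol(L, R, Z)
        quad = 0.0
        for i in range(k):
            for c in range(m):
                quad += R[i, c] * Z[i, c]
        ll += -0.5 * (m * (k * _LOG2PI + logdet) + quad)
        Vhat = np.empty((m, p))
        for c in range(m):
            row = r0 + c
            for i in range(k):
                Vhat[c, obs_idx[pi, i]] = Vsort[row, obs_idx[pi, i]]
        if nmis > 0:
            Smo = np.empty((nmis, k))
            for i in range(nmis):
                for j in range(k):
                    Smo[i, j] = Sigma[mis[i], obs_idx[pi, j]]
            for c in range(m):
                for i in range(nmis):
                    acc = mu[mis[i]]
                    for j in range(k):
                        acc += Smo[i, j] * Z[j, c]
                    Vhat[c, mis[i]] = acc
            # conditional covariance of the missing block
            SmoT = np.empty((k, nmis))
            for i in range(k):
                for j in range(nmis):
                    SmoT[i, j] = Smo[j, i]
            Q = np.empty((k, nmis))
            _solve_chol(L, SmoT, Q)
            for i in range(nmis):
                for j in range(nmis):
                    acc = Sigma[mis[i], mis[j]]
                    for t2 in range(k):
                        acc -= Smo[i, t2] * Q[t2, j]
                    sum_vv[mis[i], mis[j]] += m * acc
        for c in range(m):
            for i in range(p):
                sum_v[i] += Vhat[c, i]
                for j in range(p):
                    sum_vv[i, j] += Vhat[c, i] * Vhat[c, j]
    return ll, True, sum_v, sum_vv
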