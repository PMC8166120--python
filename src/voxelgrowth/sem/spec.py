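"""Model specifications for latent growth and parallel-process SEMs.

A model here is a linear structural equation model with a joint-normal
observed vector ``(y_1..y_T, x_1..x_q)``:

* measurement: ``y = Lambda @ eta + eps``, ``eps ~ N(0, diag(theta))``
* structure:   ``eta = alpha + B @ eta + Gamma @ x + zeta``, ``zeta ~ N(0, Psi)``
* covariates ``x`` are exogenous with a saturated mean/covariance block,
  so maximum likelihood conditions on them exactly.

``Lambda`` is fixed (growth loadings); every entry of ``alpha``, ``B``,
``Gamma``, ``Psi`` and ``theta`` is either free or fixed at a constant.
Parameter labels follow the conventional tilde notation: ``S~mfq`` is a
regression, ``I~~S`` a (co)variance, ``I~1`` a latent mean, ``y1~~y1`` a
residual variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Parameter", "SemSpec", "build_lgm_spec", "build_saturated_spec"]


@dataclass(frozen=True)
class Parameter:
    """One free parameter: where it lives and what it is called."""

    name: str
    matrix: str          # 'alpha' | 'B' | 'gamma' | 'psi' | 'theta'
    index: tuple         # position within the matrix (symmetric pairs for psi)
    start: float = 0.0


class SemSpec:
    """A fully specified SEM structure with named free parameters.

    Parameters
    ----------
    y_names, x_names, latent_names
        Observed outcome, exogenous covariate, and latent variable labels.
    lam
        Fixed loading matrix, shape ``(T, L)``.
    alpha, B, gamma, psi, theta
        Base value arrays; entries listed in ``free`` are overwritten by the
        parameter vector, all others are fixed at the given value.
    free
        Ordered list of :class:`Parameter`.
    """

    def __init__(self, y_names, x_names, latent_names, lam,
                 alpha, B, gamma, psi, theta, free):
        self.y_names = list(y_names)
        self.x_names = list(x_names)
        self.latent_names = list(latent_names)
        self.lam = np.asarray(lam, float)
        T, L = self.lam.shape
        if T != len(self.y_names) or L != len(self.latent_names):
            raise ValueError("loading matrix shape does not match variable names")
        self.alpha0 = np.asarray(alpha, float).copy()
        self.B0 = np.asarray(B, float).copy()
        self.gamma0 = np.asarray(gamma, float).reshape(L, len(self.x_names)).copy()
        self.psi0 = np.asarray(psi, float).copy()
        self.theta0 = np.asarray(theta, float).copy()
        self.free = list(free)
        names = [p.name for p in self.free]
        if len(set(names)) != len(names):
            raise ValueError("duplicate free parameter names")
        self._index = {p.name: k for k, p in enumerate(self.free)}
        self._plan = None

    # -- basic bookkeeping -------------------------------------------------
    @property
    def n_waves(self):
        return len(self.y_names)

    @property
    def n_covariates(self):
        return len(self.x_names)

    @property
    def n_latent(self):
        return len(self.latent_names)

    @property
    def n_free(self):
        return len(self.free)

    @property
    def param_names(self):
        return [p.name for p in self.free]

    def start_vector(self):
        return np.array([p.start for p in self.free])

    def n_moments(self):
        """First and second moments of the full observed vector (y, x)."""
        p = self.n_waves + self.n_covariates
        return p * (p + 3) // 2

    def n_free_total(self):
        """Free structural parameters plus the saturated covariate block."""
        q = self.n_covariates
        return self.n_free + q * (q + 3) // 2

    @property
    def df(self):
        return self.n_moments() - self.n_free_total()

    def check_identified(self):
        if self.df < 0:
            raise ValueError(
                f"model not identified: {self.n_free_total()} free parameters "
                f"exceed {self.n_moments()} observed moments")
        return self.df

    # -- parameter vector <-> matrices ------------------------------------
    def plan(self):
        """Cached index arrays mapping the free vector into the matrices
        (and back, for the analytic gradient)."""
        if self._plan is None:
            groups = {}
            for k, p in enumerate(self.free):
                groups.setdefault(p.matrix, []).append((k, p.index))
            plan = {}
            for mat, items in groups.items():
                ks = np.array([k for k, _ in items])
                idx = np.array([i for _, i in items])
                plan[mat] = (ks, idx)
            self._plan = plan
        return self._plan

    def matrices(self, params):
        """Return (alpha, B, gamma, psi, theta) with free entries filled in."""
        params = np.asarray(params, float)
        if params.shape != (self.n_free,):
            raise ValueError(
                f"expected {self.n_free} parameters, got {params.shape}")
        alpha = self.alpha0.copy()
        B = self.B0.copy()
        gamma = self.gamma0.copy()
        psi = self.psi0.copy()
        theta = self.theta0.copy()
        plan = self.plan()
        for mat, arr in (("alpha", alpha), ("B", B), ("gamma", gamma),
                         ("theta", theta)):
            if mat in plan:
                ks, idx = plan[mat]
                if idx.shape[1] == 2:
                    arr[idx[:, 0], idx[:, 1]] = params[ks]
                else:
                    arr[idx[:, 0]] = params[ks]
        if "psi" in plan:
            ks, idx = plan["psi"]
            psi[idx[:, 0], idx[:, 1]] = params[ks]
            psi[idx[:, 1], idx[:, 0]] = params[ks]
        return alpha, B, gamma, psi, theta

    def constrain(self, fixed):
        """Return a copy with the named parameters removed and fixed.

        Parameters
        ----------
        fixed : dict
            Mapping of parameter name -> fixed value.
        """
        unknown = set(fixed) - {p.name for p in self.free}
        if unknown:
            raise KeyError(f"cannot constrain unknown parameters: {sorted(unknown)}")
        alpha = self.alpha0.copy()
        B = self.B0.copy()
        gamma = self.gamma0.copy()
        psi = self.psi0.copy()
        theta = self.theta0.copy()
        mats = {"alpha": alpha, "B": B, "gamma": gamma, "psi": psi, "theta": theta}
        keep = []
        for p in self.free:
            if p.name in fixed:
                m = mats[p.matrix]
                if p.matrix == "psi":
                    i, j = p.index
                    m[i, j] = fixed[p.name]
                    m[j, i] = fixed[p.name]
                else:
                    m[p.index] = fixed[p.name]
            else:
                keep.append(p)
        return SemSpec(self.y_names, self.x_names, self.latent_names, self.lam,
                       alpha, B, gamma, psi, theta, keep)

    def param_index(self, name):
        return self._index[name]


def _default_loadings(n_waves):
    return np.arange(n_waves, dtype=float)


def build_lgm_spec(n_waves, loadings=None, covariates=(), constraints=None,
                   y_names=None, latent_prefix=""):
    """Build a linear latent growth model specification.

    The latent intercept loads 1 on every wave; the latent slope carries the
    wave coding in ``loadings`` (default ``0, 1, ..., T-1``, one unit per
    measurement occasion) with the first loading 0 so the intercept is the
    wave-1 status.  With ``covariates`` given, both latent factors are
    regressed on each covariate (a conditional growth model).

    Parameters
    ----------
    n_waves : int
        Number of measurement occasions (>= 3 for an identified model with
        free per-wave residual variances).
    loadings : sequence of float, optional
        Slope loadings, length ``n_waves``, first entry 0.
    covariates : sequence of str
        Exogenous covariate names (e.g. ``("mfq_fof", "age_c")``).
    constraints : dict, optional
        Parameter name -> fixed value (e.g. ``{"y2~~y2": 0.0}``).
    """
    if loadings is None:
        loadings = _default_loadings(n_waves)
    loadings = np.asarray(loadings, float)
    if loadings.shape != (n_waves,):
        raise ValueError("loadings length must equal n_waves")
    if loadings[0] != 0:
        raise ValueError("first slope loading must be 0 (intercept at wave 1)")
    if y_names is None:
        y_names = [f"y{t + 1}" for t in range(n_waves)]
    I = latent_prefix + "I" if latent_prefix else "I"
    S = latent_prefix + "S" if latent_prefix else "S"
    latent_names = [I, S]
    lam = np.column_stack([np.ones(n_waves), loadings])
    q = len(covariates)

    free = []
    free.append(Parameter(f"{I}~1", "alpha", (0,), 0.0))
    free.append(Parameter(f"{S}~1", "alpha", (1,), 0.0))
    for j, x in enumerate(covariates):
        free.append(Parameter(f"{I}~{x}", "gamma", (0, j), 0.0))
        free.append(Parameter(f"{S}~{x}", "gamma", (1, j), 0.0))
    free.append(Parameter(f"{I}~~{I}", "psi", (0, 0), 1.0))
    free.append(Parameter(f"{S}~~{S}", "psi", (1, 1), 1.0))
    free.append(Parameter(f"{I}~~{S}", "psi", (0, 1), 0.0))
    for t, y in enumerate(y_names):
        free.append(Parameter(f"{y}~~{y}", "theta", (t,), 1.0))

    spec = SemSpec(
        y_names, list(covariates), latent_names, lam,
        alpha=np.zeros(2), B=np.zeros((2, 2)), gamma=np.zeros((2, q)),
        psi=np.zeros((2, 2)), theta=np.zeros(n_waves), free=free)
    if constraints:
        spec = spec.constrain(dict(constraints))
    spec.check_identified()
    return spec


def build_saturated_spec(y_names, x_names):
    """Saturated conditional model: unstructured regression of y on x.

    Used as the direct-maximization route to the saturated log-likelihood
    (cross-checked against EM).  Latents are the outcomes themselves
    (identity loadings, theta fixed 0, Psi unstructured).
    """
    T = len(y_names)
    q = len(x_names)
    free = []
    for t, y in enumerate(y_names):
        free.append(Parameter(f"{y}~1", "alpha", (t,), 0.0))
    for t, y in enumerate(y_names):
        for j, x in enumerate(x_names):
            free.append(Parameter(f"{y}~{x}", "gamma", (t, j), 0.0))
    for t in range(T):
        for u in range(t, T):
            free.append(Parameter(f"{y_names[t]}~~{y_names[u]}", "psi",
                                  (t, u), 1.0 if t == u else 0.0))
    return SemSpec(
        y_names, x_names, list(y_names), np.eye(T),
        alpha=np.zeros(T), B=np.zeros((T, T)), gamma=np.zeros((T, q)),
        psi=np.zeros((T, T)), theta=np.zeros(T), free=free)
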