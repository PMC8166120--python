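"""Synthetic longitudinal cohorts with known ground truth.

Emulates the design of a three-wave aging cohort sampled roughly every 18
months: 69 baseline participants of whom 49 enroll longitudinally, thinning
to about 34 at wave 2 and 28 at wave 3 (non-monotone attendance allowed).
Covariates follow the published baseline distributions (MFQ-FoF scores on
the 0-6 scale, mean 2.99 / SD 0.91; ages 50-85, mean 68.33 / SD 7.95).
Outcomes are Fisher-z connectivity values generated from a conditional
latent growth model, so every downstream stage can be tested against the
planted parameters.  All randomness flows from one seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import SubjectRecord, center_age
from .sem.likelihood import LongTable

__all__ = [
    "GrowthTruth", "AttritionModel", "CovariateModel", "EffectCluster",
    "SimulationConfig", "generate_cohort", "generate_growth_panel",
    "generate_voxel_field", "generate_timeseries", "VoxelField",
    "records_to_frame", "write_cohort", "write_voxel_field",
]


@dataclass(frozen=True)
class GrowthTruth:
    """Population parameters of the conditional linear growth model.

    The latent intercept is the wave-1 status; the slope is change per
    measurement occasion.  ``gamma_*`` are covariate paths onto the
    intercept/slope (m = MFQ-FoF, a = age centered at 70); ``psi_*`` the
    latent disturbance (co)variances; ``theta`` the per-wave residual
    variances.  Defaults describe a plausible Fisher-z connectivity outcome
    with modest individual differences and no covariate effects.
    """

    alpha_i: float = 0.25
    alpha_s: float = -0.02
    gamma_im: float = 0.0
    gamma_sm: float = 0.0
    gamma_ia: float = 0.0
    gamma_sa: float = 0.0
    psi_ii: float = 0.02
    psi_ss: float = 0.004
    psi_is: float = 0.001
    theta: tuple = (0.02, 0.02, 0.02)

    def __post_init__(self):
        psi = self.psi_matrix()
        if np.linalg.eigvalsh(psi).min() < -1e-12:
            raise ValueError(
                f"latent disturbance matrix not positive semidefinite: {psi}")
        if any(t < 0 for t in self.theta):
            raise ValueError(f"residual variances must be >= 0: {self.theta}")

    def psi_matrix(self):
        return np.array([[self.psi_ii, self.psi_is],
                         [self.psi_is, self.psi_ss]])

    def param_dict(self):
        d = {"I~1": self.alpha_i, "S~1": self.alpha_s,
             "I~mfq_fof": self.gamma_im, "S~mfq_fof": self.gamma_sm,
             "I~age_c": self.gamma_ia, "S~age_c": self.gamma_sa,
             "I~~I": self.psi_ii, "S~~S": self.psi_ss, "I~~S": self.psi_is}
        for t, th in enumerate(self.theta):
            d[f"y{t + 1}~~y{t + 1}"] = th
        return d


@dataclass(frozen=True)
class AttritionModel:
    """Bernoulli retention at follow-up waves among longitudinal enrollees.

    ``retention`` gives the marginal retention target per follow-up wave
    (defaults 34/49 and 28/49).  ``coefficients`` are log-odds of *dropout*
    per unit of each (mean-centered) baseline covariate; the intercept per
    wave is set to the logit of the target so marginal retention stays at
    the target when the coefficients are 0.  With ``monotone`` set, wave
    t+1 attendance requires wave t attendance and conditional probabilities
    are rescaled so the marginal targets are preserved (which requires
    non-increasing targets).
    """

    retention: tuple = (34 / 49, 28 / 49)
    coefficients: dict = field(default_factory=dict)   # covariate -> log-odds
    monotone: bool = False

    def __post_init__(self):
        if any(not (0 <= r <= 1) for r in self.retention):
            raise ValueError("retention targets must be probabilities")
        if self.monotone:
            prev = 1.0
            for r in self.retention:
                if r > prev + 1e-12:
                    raise ValueError(
                        "monotone attrition needs non-increasing retention "
                        f"targets, got {self.retention}")
                prev = r
        known = {"mfq_fof", "age"}
        bad = set(self.coefficients) - known
        if bad:
            raise ValueError(f"unknown attrition covariates: {sorted(bad)}")


@dataclass(frozen=True)
class CovariateModel:
    """Truncated-normal baseline covariates (defaults follow Table-1-style
    published moments)."""

    mfq_mean: float = 2.99
    mfq_sd: float = 0.91
    mfq_bounds: tuple = (0.0, 6.0)
    age_mean: float = 68.33
    age_sd: float = 7.95
    age_bounds: tuple = (50.0, 85.0)
    correlation: float = 0.0     # optional mfq-age dependence


@dataclass(frozen=True)
class EffectCluster:
    """A spherical region of voxels sharing a planted slope-on-MFQ effect."""

    center: tuple                # voxel indices (i, j, k)
    radius: float                # voxels
    gamma_sm: float


@dataclass(frozen=True)
class SimulationConfig:
    n_subjects: int = 69
    n_longitudinal: int = 49
    n_waves: int = 3
    wave_spacing_months: float = 18.0
    loadings: tuple | None = None        # default 0, 1, ..., T-1
    covariates: CovariateModel = field(default_factory=CovariateModel)
    truth: GrowthTruth = field(default_factory=GrowthTruth)
    attrition: AttritionModel = field(default_factory=AttritionModel)
    grid_dims: tuple = (24, 24, 24)
    voxel_size_mm: float = 2.0
    effect_clusters: tuple = ()
    #: when set, emit per-subject Likert items (1-7) whose derived score
    #: replaces the directly drawn MFQ-FoF value (exercises item scoring)
    mfq_item_count: int | None = None
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.n_longitudinal <= self.n_subjects):
            raise ValueError("need 0 < n_longitudinal <= n_subjects")
        if self.n_waves < 2:
            raise ValueError("need at least two waves")
        if len(self.attrition.retention) != self.n_waves - 1:
            raise ValueError("attrition needs one retention target per "
                             "follow-up wave")
        if len(self.truth.theta) != self.n_waves:
            raise ValueError("truth.theta needs one entry per wave")
        for c in self.effect_clusters:
            if any(not (0 <= c.center[d] < self.grid_dims[d])
                   for d in range(3)):
                raise ValueError(f"effect cluster {c.center} outside grid "
                                 f"{self.grid_dims}")

    def wave_loadings(self):
        if self.loadings is not None:
            lam = np.asarray(self.loadings, float)
        else:
            lam = np.arange(self.n_waves, dtype=float)
        return lam

    def affine(self):
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size_mm
        return aff


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    dist = stats.truncnorm(a, b, loc=mean, scale=sd)
    return dist.ppf(rng.uniform(size=size))


def generate_cohort(config: SimulationConfig, rng=None):
    """Draw baseline covariates and per-wave attendance for one cohort."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cov = config.covariates
    n = config.n_subjects
    mfq = _truncnorm(rng, cov.mfq_mean, cov.mfq_sd, *cov.mfq_bounds, size=n)
    age = _truncnorm(rng, cov.age_mean, cov.age_sd, *cov.age_bounds, size=n)
    if cov.correlation:
        # rank-based coupling keeps both marginals truncated-normal
        r = cov.correlation
        z = r * stats.norm.ppf(stats.rankdata(mfq) / (n + 1)) \
            + np.sqrt(1 - r * r) * rng.standard_normal(n)
        age = np.sort(age)[np.argsort(np.argsort(z))]

    att = config.attrition
    centered = {"mfq_fof": mfq - mfq.mean(), "age": age - age.mean()}
    present = np.zeros((n, config.n_waves), bool)
    present[:, 0] = True
    longitudinal = np.zeros(n, bool)
    longitudinal[:config.n_longitudinal] = True
    prev_target = 1.0
    prev_present = present[:, 0].copy()
    for w, target in enumerate(att.retention, start=1):
        if att.monotone:
            cond = target / prev_target if prev_target > 0 else 0.0
            eta = np.full(n, _logit(cond))
        else:
            eta = np.full(n, _logit(target))
        for name, beta in att.coefficients.items():
            # coefficients are dropout log-odds; subtract from retention
            eta = eta - beta * centered[name]
        p_ret = 1.0 / (1.0 + np.exp(-eta))
        stay = rng.uniform(size=n) < p_ret
        present[:, w] = longitudinal & stay
        if att.monotone:
            present[:, w] &= prev_present
            prev_present = present[:, w].copy()
            prev_target = target
    records = []
    for i in range(n):
        items = None
        score = float(mfq[i])
        if config.mfq_item_count:
            items = _items_for_score(rng, score, config.mfq_item_count)
            from .cohort import score_mfq
            score = score_mfq(items)
        records.append(SubjectRecord(
            subject_id=f"sub-{i + 1:03d}", age_years=float(age[i]),
            mfq_fof=score, wave_present=tuple(present[i]),
            mfq_items=items))
    return records


def _items_for_score(rng, score, k):
    """Likert items (1-7) whose inverted-average score scatters around the
    target; the derived score is recomputed from the items afterwards."""
    raw = rng.normal(7.0 - score, 1.0, size=k)
    return tuple(int(v) for v in np.clip(np.round(raw), 1, 7))


def _psd_sqrt(psi):
    """Square root of a PSD matrix; exact zeros stay exact (boundary cases)."""
    psi = np.asarray(psi, float)
    w, Q = np.linalg.eigh(psi)
    scale = max(abs(w).max(), 1.0)
    if w.min() < -1e-10 * scale:
        raise ValueError(
            f"latent disturbance matrix not positive semidefinite: {psi}")
    return Q @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ Q.T


def _logit(p):
    p = min(max(p, 1e-12), 1 - 1e-12)
    return np.log(p / (1 - p))


def covariate_matrix(records):
    """(n, 2) matrix of (mfq_fof, age centered at 70)."""
    return np.array([[r.mfq_fof, center_age(r.age_years)] for r in records])


def generate_growth_panel(records, truth, loadings=None, seed=0, rng=None):
    """Simulate one voxel's longitudinal outcome panel under ``truth``.

    ``y_it = (a_I + g_Im m_i + g_Ia a_i + z_Ii)
             + lam_t (a_S + g_Sm m_i + g_Sa a_i + z_Si) + e_it``
    with cells masked by each subject's attendance.  Returns a
    :class:`~voxelgrowth.sem.LongTable` with covariates (mfq_fof, age_c).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n_waves = len(records[0].wave_present)
    if loadings is None:
        loadings = np.arange(n_waves, dtype=float)
    loadings = np.asarray(loadings, float)
    if loadings.shape != (n_waves,):
        raise ValueError("loadings length must equal the number of waves")
    if loadings[0] != 0:
        raise ValueError("first loading must be 0 (intercept at wave 1)")
    X = covariate_matrix(records)
    n = len(records)
    zeta = rng.standard_normal((n, 2)) @ _psd_sqrt(truth.psi_matrix()).T
    eta = np.column_stack([
        truth.alpha_i + truth.gamma_im * X[:, 0] + truth.gamma_ia * X[:, 1],
        truth.alpha_s + truth.gamma_sm * X[:, 0] + truth.gamma_sa * X[:, 1],
    ]) + zeta
    lam = np.column_stack([np.ones(n_waves), loadings])
    eps = rng.standard_normal((n, n_waves)) * np.sqrt(np.asarray(truth.theta))
    Y = eta @ lam.T + eps
    mask = np.array([r.wave_present for r in records])
    Y[~mask] = np.nan
    return LongTable(Y, X, y_names=[f"y{t+1}" for t in range(n_waves)],
                     x_names=["mfq_fof", "age_c"])


@dataclass
class VoxelField:
    """Per-voxel longitudinal panels on a 3D grid, with the planted truth."""

    data: np.ndarray          # (n_subjects, n_waves, nx, ny, nz)
    truth_mask: np.ndarray    # (nx, ny, nz) bool
    gamma_map: np.ndarray     # (nx, ny, nz) planted slope-on-MFQ values
    records: list
    config: SimulationConfig


def generate_voxel_field(config: SimulationConfig, records=None, rng=None):
    """Simulate a 3D field of independent growth panels with planted
    spherical effect clusters.

    Background voxels have a zero slope-on-MFQ path; voxels inside each
    :class:`EffectCluster` carry that cluster's planted ``gamma_sm``.
    Overlapping clusters with conflicting effects are rejected.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if records is None:
        records = generate_cohort(config, rng=rng)
    dims = config.grid_dims
    gamma_map = np.zeros(dims)
    claimed = np.zeros(dims, bool)
    grid = np.indices(dims).reshape(3, -1).T
    for c in config.effect_clusters:
        d2 = ((grid - np.asarray(c.center)) ** 2).sum(axis=1)
        inside = (d2 <= c.radius ** 2).reshape(dims)
        conflict = claimed & inside & ~np.isclose(gamma_map, c.gamma_sm)
        if conflict.any():
            raise ValueError(
                f"effect cluster at {c.center} overlaps another cluster "
                "with a different planted effect")
        gamma_map[inside] = c.gamma_sm
        claimed |= inside
    truth_mask = claimed

    n = len(records)
    T = config.n_waves
    lam = np.column_stack([np.ones(T), config.wave_loadings()])
    X = covariate_matrix(records)
    tr = config.truth
    base = dataclasses.replace(tr, gamma_sm=0.0)
    nvox = int(np.prod(dims))
    # latent disturbances and residuals, independent across voxels
    zeta = rng.standard_normal((nvox, n, 2)) @ _psd_sqrt(tr.psi_matrix()).T
    eta0 = np.column_stack([
        base.alpha_i + base.gamma_im * X[:, 0] + base.gamma_ia * X[:, 1],
        base.alpha_s + base.gamma_sa * X[:, 1],
    ])                                                    # (n, 2)
    eta = eta0[None] + zeta                               # (nvox, n, 2)
    eta[:, :, 1] += gamma_map.reshape(-1, 1) * X[:, 0]
    eps = rng.standard_normal((nvox, n, T)) * np.sqrt(np.asarray(tr.theta))
    Y = eta @ lam.T + eps                                 # (nvox, n, T)
    mask = np.array([r.wave_present for r in records])    # (n, T)
    Y[:, ~mask] = np.nan
    data = np.moveaxis(Y.reshape(*dims, n, T), (3, 4), (0, 1))
    return VoxelField(data=np.ascontiguousarray(data), truth_mask=truth_mask,
                      gamma_map=gamma_map, records=records, config=config)


def generate_timeseries(grid_dims, roi_voxels, target_voxels=(),
                        target_r=0.0, n_volumes=200, seed=0, rng=None):
    """Toy 4D image for exercising seed-map construction.

    All ROI voxels carry one common unit-variance signal (so the ROI mean
    is that signal exactly); each target voxel is an independent mixture
    ``r * signal + sqrt(1 - r^2) * noise`` with population correlation
    ``target_r`` against the ROI mean; all other voxels are white noise.
    Returns an array of shape ``(*grid_dims, n_volumes)``.
    """
    if abs(target_r) >= 1:
        raise ValueError("|target_r| must be < 1")
    if n_volumes < 30:
        raise ValueError("need at least 30 volumes")
    if rng is None:
        rng = np.random.default_rng(seed)
    img = rng.standard_normal((*grid_dims, n_volumes))
    signal = rng.standard_normal(n_volumes)
    for v in roi_voxels:
        img[tuple(v)] = signal
    for v in target_voxels:
        img[tuple(v)] = (target_r * signal
                         + np.sqrt(1 - target_r ** 2)
                         * rng.standard_normal(n_volumes))
    return img


# ---------------------------------------------------------------------------
# writers (TSV / NIfTI / JSON interchange)

def records_to_frame(records):
    """Long-format covariate table: one row per subject x wave."""
    rows = []
    for r in records:
        for w, present in enumerate(r.wave_present, start=1):
            row = {"subject": r.subject_id, "wave": w, "age": r.age_years,
                   "mfq_fof": r.mfq_fof, "present": int(present)}
            if r.mfq_items:
                for j, it in enumerate(r.mfq_items, start=1):
                    row[f"mfq_item_{j}"] = it
            for name, vals in r.cognitive.items():
                row[name] = vals[w - 1]
            rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(records, path):
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def write_voxel_field(field: VoxelField, out_dir):
    """Write per-subject-wave NIfTI maps, a manifest, and the truth file."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = field.config.affine()
    rows = []
    for i, r in enumerate(field.records):
        for w, present in enumerate(r.wave_present):
            if not present:
                continue
            p = out / f"{r.subject_id}_wave-{w + 1}_fcmap.nii.gz"
            nib.save(nib.Nifti1Image(
                field.data[i, w].astype(np.float32), aff), p)
            rows.append({"subject": r.subject_id, "wave": w + 1,
                         "path": str(p)})
    pd.DataFrame(rows).to_csv(out / "manifest.tsv", sep="\t", index=False)
    write_cohort(field.records, out / "covariates.tsv")
    mask_path = out / "truth_mask.nii.gz"
    nib.save(nib.Nifti1Image(field.truth_mask.astype(np.uint8), aff),
             mask_path)
    truth = {"truth_mask": str(mask_path),
             "gamma_sm_clusters": [
                 {"center": list(c.center), "radius": c.radius,
                  "gamma_sm": c.gamma_sm}
                 for c in field.config.effect_clusters],
             "growth_truth": dataclasses.asdict(field.config.truth)}
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
    return out / "manifest.tsv"
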