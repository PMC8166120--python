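"""Mass-univariate growth modeling over 3D statistic grids.

Runs the FIML growth-SEM engine independently at every in-mask voxel of
stacked longitudinal connectivity maps, producing aligned 3D statistic
volumes; masks them by SEM fit quality (RMSEA <= .10, CFI >= .90,
SRMR <= .10); applies voxel-p + cluster-extent correction (p < .001,
240 mm^3 by default); and reports the peak-voxel model per surviving
cluster, with the unconditional-model slope-variance range across the
cluster for context.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .sem.fit import apply_heywood_rule, fit_sem
from .sem.likelihood import LongTable
from .sem.spec import build_lgm_spec

__all__ = ["StatMapSet", "Cluster", "VoxelPanels", "stack_maps",
           "fit_voxelwise", "fit_quality_mask", "cluster_correct",
           "select_peak", "save_statmaps", "cluster_table"]

STAT_NAMES = ("estimate", "se", "z", "p", "chi2", "df", "cfi", "rmsea",
              "srmr", "converged", "constrained")


@dataclass
class StatMapSet:
    """Aligned 3D statistic volumes from one voxelwise run."""

    volumes: dict                      # name -> (nx, ny, nz) array
    affine: np.ndarray
    mask: np.ndarray                   # analysis mask actually fit
    target: str                        # parameter mapped into estimate/se/z/p
    seed: int
    report: dict = field(default_factory=dict)

    @property
    def voxel_volume_mm3(self):
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def __getitem__(self, name):
        return self.volumes[name]


@dataclass
class Cluster:
    """A suprathreshold connected component."""

    label: int
    voxels: np.ndarray                 # (m, 3) indices
    volume_mm3: float
    min_p: float
    peak_voxel: tuple | None = None
    peak_mm: tuple | None = None
    peak_fit: object | None = None
    peak_estimate: float = np.nan
    slope_var_range: tuple | None = None
    slope_var_p_range: tuple | None = None
    warnings: list = field(default_factory=list)

    @property
    def n_voxels(self):
        return self.voxels.shape[0]


class VoxelPanels:
    """Per-voxel longitudinal panels over a common grid.

    Wraps a ``(n_subjects, n_waves, nx, ny, nz)`` array plus the covariate
    matrix; yields a :class:`LongTable` per voxel.  Built either from a
    synthetic field or from NIfTI maps via :func:`stack_maps`.
    """

    def __init__(self, data, X, affine, mask=None, x_names=("mfq_fof", "age_c"),
                 subjects=None):
        self.data = data
        self.X = np.asarray(X, float)
        self.affine = np.asarray(affine, float)
        self.grid = data.shape[2:]
        if mask is None:
            mask = np.ones(self.grid, bool)
        self.mask = np.asarray(mask).astype(bool)
        self.x_names = list(x_names)
        self.subjects = subjects
        self.n_subjects, self.n_waves = data.shape[:2]

    @classmethod
    def from_field(cls, fld, mask=None):
        from .simulate import covariate_matrix
        return cls(fld.data, covariate_matrix(fld.records),
                   fld.config.affine(), mask=mask)

    def panel(self, ijk):
        i, j, k = ijk
        return LongTable(self.data[:, :, i, j, k], self.X,
                         x_names=self.x_names)

    def __iter__(self):
        for ijk in np.argwhere(self.mask):
            yield tuple(ijk), self.panel(tuple(ijk))


def stack_maps(manifest, covariates, mask=None, affine_atol=1e-4):
    """Assemble per-voxel longitudinal panels from NIfTI map files.

    ``manifest`` (TSV path or DataFrame: subject, wave, path) names one 3D
    map per attended subject-wave; ``covariates`` (TSV path or DataFrame)
    carries ``subject, wave, age, mfq_fof, present``.  Waves without a map
    become missing outcomes.  All maps must share grid and affine; a
    mismatch is an error naming the offending file.
    """
    import nibabel as nib

    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest, sep="\t")
    if not isinstance(covariates, pd.DataFrame):
        covariates = pd.read_csv(covariates, sep="\t")
    base = covariates.sort_values(["subject", "wave"])
    subjects = list(dict.fromkeys(base["subject"]))
    n_waves = int(base["wave"].max())
    missing = set(manifest["subject"]) - set(subjects)
    if missing:
        raise ValueError(
            f"manifest subjects absent from covariate table: {sorted(missing)}")
    first = covariates.drop_duplicates("subject").set_index("subject")
    X = np.column_stack([first.loc[subjects, "mfq_fof"].to_numpy(float),
                         first.loc[subjects, "age"].to_numpy(float) - 70.0])
    shape = None
    affine = None
    data = None
    sindex = {s: i for i, s in enumerate(subjects)}
    for row in manifest.itertuples():
        img = nib.load(row.path)
        if shape is None:
            shape = img.shape
            affine = img.affine
            data = np.full((len(subjects), n_waves, *shape), np.nan,
                           dtype=np.float32)
        elif img.shape != shape or not np.allclose(img.affine, affine,
                                                   atol=affine_atol):
            raise ValueError(f"grid mismatch in map file: {row.path}")
        data[sindex[row.subject], int(row.wave) - 1] = img.get_fdata()
    if data is None:
        raise ValueError("manifest is empty")
    if mask is not None and not isinstance(mask, np.ndarray):
        mimg = nib.load(str(mask))
        if mimg.shape != shape:
            raise ValueError(f"grid mismatch in mask file: {mask}")
        mask = mimg.get_fdata() > 0
    return VoxelPanels(data, X, affine, mask=mask, subjects=subjects)


def _fit_one_voxel(spec, table, target, seed, n_starts, heywood):
    """Fit one voxel's panel; return the scalar statistics row."""
    res = fit_sem(spec, table, n_starts=n_starts, seed=seed,
                  rmsea_interval=False)
    if heywood and res.converged:
        res = apply_heywood_rule(res, spec, table, n_starts=n_starts,
                                 seed=seed, rmsea_interval=False)
    if not res.converged:
        return None
    out = {"estimate": res.estimates.get(target, np.nan),
           "se": res.se.get(target, np.nan),
           "z": res.z.get(target, np.nan),
           "p": res.p.get(target, np.nan),
           "converged": 1.0,
           "constrained": float(bool(res.constrained_params))}
    if res.fit is not None:
        out.update(chi2=res.fit.chi2, df=res.fit.df, cfi=res.fit.cfi,
                   rmsea=res.fit.rmsea, srmr=res.fit.srmr)
    return out


def fit_voxelwise(panels, spec=None, target=None, seed=0, n_starts=1,
                  heywood=True, n_jobs=1, progress=False):
    """Fit the growth SEM at every in-mask voxel.

    Returns a :class:`StatMapSet` with the target-parameter estimate, its
    Wald statistics, the fit-index volumes, and convergence/constraint
    flags.  Voxels where the Heywood rule fired are flagged ``constrained``
    (the reporting convention keeps peak models constraint-free); per-voxel
    non-convergence is recorded, never fatal.  Voxels are independent, so
    the run parallelizes over ``n_jobs`` workers; output is deterministic
    given ``seed`` and identical for any voxel order or worker count.
    """
    if spec is None:
        spec = build_lgm_spec(panels.n_waves, covariates=tuple(panels.x_names))
    if target is None:
        target = f"S~{panels.x_names[0]}" if panels.x_names else "S~1"
    grid = panels.grid
    vols = {name: np.full(grid, np.nan) for name in STAT_NAMES}
    vols["converged"] = np.zeros(grid)
    vols["constrained"] = np.zeros(grid)
    voxels = [tuple(v) for v in np.argwhere(panels.mask)]
    if n_jobs != 1:
        from joblib import Parallel, delayed
        rows = Parallel(n_jobs=n_jobs, batch_size=256)(
            delayed(_fit_one_voxel)(spec, panels.panel(ijk), target, seed,
                                    n_starts, heywood)
            for ijk in voxels)
    else:
        rows = []
        for i, ijk in enumerate(voxels):
            if progress and i % 1000 == 0:
                print(f"  voxel {i}/{len(voxels)}", flush=True)
            rows.append(_fit_one_voxel(spec, panels.panel(ijk), target,
                                       seed, n_starts, heywood))
    n_conv = n_constrained = 0
    for ijk, row in zip(voxels, rows):
        if row is None:
            continue
        n_conv += 1
        n_constrained += row["constrained"] > 0
        for name, v in row.items():
            vols[name][ijk] = v
    report = {"voxels_in_mask": int(panels.mask.sum()),
              "voxels_fit": len(voxels), "converged": n_conv,
              "constrained": int(n_constrained), "target": target}
    return StatMapSet(volumes=vols, affine=panels.affine, mask=panels.mask,
                      target=target, seed=seed, report=report)


def fit_quality_mask(maps: StatMapSet, rmsea_max=0.10, cfi_min=0.90,
                     srmr_max=0.10):
    """Binary volume: 1 where the SEM fit passes all three criteria.

    Thresholds are closed (RMSEA <= .10, CFI >= .90, SRMR <= .10), and a
    voxel must have converged to qualify.
    """
    for name in ("rmsea", "cfi", "srmr", "converged"):
        if name not in maps.volumes:
            raise KeyError(f"missing statistic volume: {name}")
    with np.errstate(invalid="ignore"):
        ok = ((maps["rmsea"] <= rmsea_max) & (maps["cfi"] >= cfi_min)
              & (maps["srmr"] <= srmr_max) & (maps["converged"] > 0))
    return ok.astype(np.uint8)


_STRUCTURES = {6: 1, 18: 2, 26: 3}


def cluster_correct(p_volume, quality_mask=None, voxel_p=0.001,
                    min_volume_mm3=240.0, affine=None, voxel_volume_mm3=None,
                    connectivity=6):
    """Voxel-p threshold + cluster-extent correction.

    Thresholds ``p < voxel_p`` within the quality mask, labels connected
    components (face connectivity by default), and keeps components whose
    volume reaches ``min_volume_mm3`` (>= 30 voxels at 2-mm isotropic for
    the 240 mm^3 default).  Returns clusters sorted by descending size.
    """
    p_volume = np.asarray(p_volume, float)
    if voxel_volume_mm3 is None:
        if affine is None:
            raise ValueError("need affine or voxel_volume_mm3")
        voxel_volume_mm3 = float(abs(np.linalg.det(
            np.asarray(affine)[:3, :3])))
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")
    structure = ndimage.generate_binary_structure(3, _STRUCTURES[connectivity])
    with np.errstate(invalid="ignore"):
        supra = p_volume < voxel_p
    if quality_mask is not None:
        supra &= np.asarray(quality_mask) > 0
    labels, n = ndimage.label(supra, structure=structure)
    clusters = []
    for lab in range(1, n + 1):
        vox = np.argwhere(labels == lab)
        vol = vox.shape[0] * voxel_volume_mm3
        if vol + 1e-9 < min_volume_mm3:
            continue
        pmin = float(np.nanmin(p_volume[tuple(vox.T)]))
        clusters.append(Cluster(label=lab, voxels=vox, volume_mm3=vol,
                                min_p=pmin))
    clusters.sort(key=lambda c: (-c.n_voxels, c.label))
    for c in clusters:       # reporting contract, asserted on every run
        members = tuple(c.voxels.T)
        assert c.volume_mm3 + 1e-9 >= min_volume_mm3
        assert bool(np.all(p_volume[members] < voxel_p))
        if quality_mask is not None:
            assert bool(np.all(np.asarray(quality_mask)[members] > 0))
    return clusters


def select_peak(cluster: Cluster, maps: StatMapSet, panels: VoxelPanels = None,
                spec=None, seed=0):
    """Report the peak-voxel model for a cluster.

    The peak is the member voxel with the largest absolute target-parameter
    estimate among voxels where no Heywood constraint fired.  When panels
    are available the full conditional model is refit there and the
    unconditional (no-covariate) model is refit across all member voxels to
    report the latent-slope-variance and p ranges.  If every member was
    constrained the cluster is returned peakless with a warning.
    """
    if cluster.n_voxels == 0:
        raise ValueError("empty cluster")
    est = maps["estimate"][tuple(cluster.voxels.T)]
    constrained = maps["constrained"][tuple(cluster.voxels.T)] > 0
    ok = ~constrained & np.isfinite(est)
    if not ok.any():
        cluster.warnings.append(
            "every member voxel required a variance constraint; no peak "
            "model reported")
        return cluster
    masked = np.where(ok, np.abs(est), -np.inf)
    k = int(np.argmax(masked))
    peak = tuple(int(v) for v in cluster.voxels[k])
    cluster.peak_voxel = peak
    cluster.peak_estimate = float(est[k])
    A = maps.affine
    cluster.peak_mm = tuple((A[:3, :3] @ np.array(peak) + A[:3, 3]).tolist())
    if panels is not None:
        if spec is None:
            spec = build_lgm_spec(panels.n_waves,
                                  covariates=tuple(panels.x_names))
        table = panels.panel(peak)
        fit = fit_sem(spec, table, seed=seed)
        fit = apply_heywood_rule(fit, spec, table, seed=seed)
        cluster.peak_fit = fit
        uspec = build_lgm_spec(panels.n_waves)
        sv, pv = [], []
        for vox in cluster.voxels:
            t = _drop_covariates(panels.panel(tuple(vox)))
            ufit = fit_sem(uspec, t, seed=seed, compute_fit_indices=False)
            if ufit.converged and "S~~S" in ufit.estimates:
                sv.append(ufit.estimates["S~~S"])
                pv.append(ufit.p.get("S~~S", np.nan))
        if sv:
            cluster.slope_var_range = (float(np.min(sv)), float(np.max(sv)))
            pv = [p for p in pv if np.isfinite(p)]
            if pv:
                cluster.slope_var_p_range = (float(np.min(pv)),
                                             float(np.max(pv)))
    return cluster


def _drop_covariates(table):
    """Outcome-only view for unconditional refits (subjects with no
    observed wave cannot contribute without covariates)."""
    keep = table.obs.any(axis=1)
    return LongTable(table.Y[keep], None, y_names=table.y_names)


# ---------------------------------------------------------------------------
# output writers

def save_statmaps(maps: StatMapSet, out_dir):
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, vol in maps.volumes.items():
        nib.save(nib.Nifti1Image(vol.astype(np.float32), maps.affine),
                 out / f"stat-{name}.nii.gz")
    (out / "run_report.json").write_text(json.dumps(maps.report, indent=2))
    return out


def cluster_table(clusters):
    rows = []
    for c in clusters:
        rows.append({
            "cluster": c.label, "n_voxels": c.n_voxels,
            "volume_mm3": c.volume_mm3, "min_p": c.min_p,
            "peak_i": c.peak_voxel[0] if c.peak_voxel else np.nan,
            "peak_j": c.peak_voxel[1] if c.peak_voxel else np.nan,
            "peak_k": c.peak_voxel[2] if c.peak_voxel else np.nan,
            "peak_x_mm": c.peak_mm[0] if c.peak_mm else np.nan,
            "peak_y_mm": c.peak_mm[1] if c.peak_mm else np.nan,
            "peak_z_mm": c.peak_mm[2] if c.peak_mm else np.nan,
            "peak_estimate": c.peak_estimate,
            "slope_var_min": c.slope_var_range[0] if c.slope_var_range else np.nan,
            "slope_var_max": c.slope_var_range[1] if c.slope_var_range else np.nan,
        })
    return pd.DataFrame(rows)
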