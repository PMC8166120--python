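"""Seed-based functional connectivity maps.

Builds spherical seed regions (12-mm diameter by default) on the analysis
grid, optionally regresses the global signal out of a preprocessed 4D
image, and computes whole-brain Fisher-z seed-correlation maps: the Pearson
correlation between the ROI-mean time series and every gray-matter voxel's
series, passed through ``atanh``.  Inputs are assumed preprocessed and
co-registered on a common grid; grid mismatch is an error, never silently
resampled.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SeedSpec", "ConnectivityMap", "load_seed_table",
           "make_sphere_roi", "regress_global_signal", "seed_map",
           "fisher_z", "DEFAULT_SEED_TABLE"]

#: Packaged seed table (label, MNI mm coordinates, diameter).
DEFAULT_SEED_TABLE = Path(__file__).parent / "data" / "seeds.tsv"

_R_CLAMP = 1.0 - 1e-7


@dataclass(frozen=True)
class SeedSpec:
    """A spherical seed region: label, MNI center (mm), diameter (mm)."""

    label: str
    center_mm: tuple
    diameter_mm: float = 12.0

    def __post_init__(self):
        if self.diameter_mm <= 0:
            raise ValueError("seed diameter must be positive")


@dataclass
class ConnectivityMap:
    """A 3D Fisher-z map with its provenance and validity mask."""

    values: np.ndarray          # (nx, ny, nz); NaN where undefined
    defined: np.ndarray         # bool mask of valid (finite) voxels
    clamped: np.ndarray         # bool mask of |r| = 1 voxels
    affine: np.ndarray
    subject: str | None = None
    wave: int | None = None
    seed_label: str | None = None


def load_seed_table(path=DEFAULT_SEED_TABLE):
    """Read a seed TSV (columns: label, x, y, z, diameter) into SeedSpecs."""
    tab = pd.read_csv(path, sep="\t")
    return [SeedSpec(row.label, (row.x, row.y, row.z), row.diameter)
            for row in tab.itertuples()]


def make_sphere_roi(seed: SeedSpec, shape, affine, gray_matter_mask=None):
    """Voxels whose center lies within ``diameter/2`` mm of the seed center,
    intersected with the gray-matter mask.

    Returns an ``(m, 3)`` integer array of voxel indices.  Raises if the
    intersection is empty (e.g. seed outside the mask).
    """
    affine = np.asarray(affine, float)
    shape = tuple(shape)
    center_vox = np.linalg.solve(affine[:3, :3],
                                 np.asarray(seed.center_mm, float)
                                 - affine[:3, 3])
    if np.any(center_vox < -0.5) or np.any(center_vox > np.array(shape) - 0.5):
        raise ValueError(
            f"seed '{seed.label}' center {seed.center_mm} mm maps outside "
            f"the grid {shape}")
    idx = np.indices(shape).reshape(3, -1).T
    mm = idx @ affine[:3, :3].T + affine[:3, 3]
    d2 = ((mm - np.asarray(seed.center_mm, float)) ** 2).sum(axis=1)
    inside = d2 <= (seed.diameter_mm / 2.0) ** 2
    if gray_matter_mask is not None:
        gm = np.asarray(gray_matter_mask).astype(bool).reshape(-1)
        inside &= gm
    vox = idx[inside]
    if vox.shape[0] == 0:
        raise ValueError(
            f"seed '{seed.label}' has no voxels inside grid/mask")
    return vox


def regress_global_signal(image_4d, brain_mask=None):
    """Residualize every voxel series on (intercept, global mean series).

    The global signal is the mean over in-mask voxels at each volume.  The
    output is orthogonal to the global signal; constant offsets are
    absorbed by the intercept.  A constant global signal is degenerate and
    raises.
    """
    img = np.asarray(image_4d, float)
    if img.ndim != 4 or img.shape[3] < 2:
        raise ValueError("need a 4D image with >= 2 volumes")
    if brain_mask is None:
        brain_mask = np.ones(img.shape[:3], bool)
    brain_mask = np.asarray(brain_mask).astype(bool)
    g = img[brain_mask].mean(axis=0)
    if np.ptp(g) == 0:
        raise ValueError("global signal is constant; nothing to regress")
    design = np.column_stack([np.ones_like(g), g])
    flat = img.reshape(-1, img.shape[3])
    beta, *_ = np.linalg.lstsq(design, flat.T, rcond=None)
    resid = flat.T - design @ beta
    return resid.T.reshape(img.shape)


def fisher_z(r):
    """Fisher z-transform ``atanh(r)``; ``|r| = 1`` clamped to finite values.

    Exact unit correlations are mapped through ``atanh(1 - 1e-7)`` so
    degenerate voxels stay finite in downstream maps; callers can detect
    them via the clamp mask returned by :func:`seed_map`.
    """
    r = np.asarray(r, float)
    if np.any(np.abs(r) > 1 + 1e-12):
        raise ValueError("correlation outside [-1, 1]")
    return np.arctanh(np.clip(r, -_R_CLAMP, _R_CLAMP))


def seed_map(image_4d, roi_voxels, gray_matter_mask=None, affine=None,
             subject=None, wave=None, seed_label=None):
    """Whole-brain Fisher-z seed-correlation map.

    For every in-mask voxel, the Pearson correlation between the ROI-mean
    series and the voxel series, Fisher z-transformed.  Zero-variance voxel
    series are flagged undefined (NaN), never +/-inf; ``|r| = 1`` voxels
    are clamped and flagged.
    """
    img = np.asarray(image_4d, float)
    if img.ndim != 4 or img.shape[3] < 3:
        raise ValueError("need a 4D image with >= 3 volumes")
    roi_voxels = np.atleast_2d(np.asarray(roi_voxels, int))
    if roi_voxels.shape[0] == 0:
        raise ValueError("ROI is empty")
    if gray_matter_mask is None:
        gray_matter_mask = np.ones(img.shape[:3], bool)
    gm = np.asarray(gray_matter_mask).astype(bool)
    ref = img[roi_voxels[:, 0], roi_voxels[:, 1], roi_voxels[:, 2]].mean(axis=0)
    refc = ref - ref.mean()
    ref_ss = refc @ refc
    if ref_ss == 0:
        raise ValueError("ROI mean series has zero variance")
    flat = img[gm]
    flatc = flat - flat.mean(axis=1, keepdims=True)
    ss = np.einsum("ij,ij->i", flatc, flatc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (flatc @ refc) / np.sqrt(ss * ref_ss)
    r = np.clip(r, -1.0, 1.0)
    undefined = ss == 0
    clamped = (np.abs(r) >= _R_CLAMP) & ~undefined
    z = np.full(img.shape[:3], np.nan)
    zvals = fisher_z(np.where(undefined, 0.0, r))
    zvals[undefined] = np.nan
    z[gm] = zvals
    defined = np.zeros(img.shape[:3], bool)
    defined[gm] = ~undefined
    clamp_vol = np.zeros(img.shape[:3], bool)
    clamp_vol[gm] = clamped
    return ConnectivityMap(values=z, defined=defined, clamped=clamp_vol,
                           affine=np.eye(4) if affine is None else affine,
                           subject=subject, wave=wave, seed_label=seed_label)
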