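"""Voxelwise driver, fit-quality masking, cluster correction, peak models."""

import numpy as np
import pytest

from voxelgrowth import EffectCluster, SimulationConfig
from voxelgrowth.simulate import generate_voxel_field, write_voxel_field
from voxelgrowth.voxelwise import (Cluster, StatMapSet, VoxelPanels,
                                   cluster_correct, cluster_table,
                                   fit_quality_mask, fit_voxelwise,
                                   select_peak, stack_maps)


def small_field(grid=5, seed=3, clusters=()):
    cfg = SimulationConfig(grid_dims=(grid, grid, grid), seed=seed,
                           effect_clusters=clusters)
    return generate_voxel_field(cfg)


def flood_fill_components(binary, connectivity=6):
    """Brute-force BFS labeling oracle."""
    offs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1),
            (0, 0, -1)]
    if connectivity >= 18:
        offs += [(a, b, 0) for a in (-1, 1) for b in (-1, 1)] + \
                [(a, 0, b) for a in (-1, 1) for b in (-1, 1)] + \
                [(0, a, b) for a in (-1, 1) for b in (-1, 1)]
    if connectivity == 26:
        offs += [(a, b, c) for a in (-1, 1) for b in (-1, 1)
                 for c in (-1, 1)]
    seen = np.zeros_like(binary, bool)
    comps = []
    for start in map(tuple, np.argwhere(binary)):
        if seen[start]:
            continue
        comp = set()
        stack = [start]
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.add(v)
            for o in offs:
                w = (v[0] + o[0], v[1] + o[1], v[2] + o[2])
                if all(0 <= w[d] < binary.shape[d] for d in range(3)) \
                        and binary[w] and not seen[w]:
                    seen[w] = True
                    stack.append(w)
        comps.append(frozenset(comp))
    return set(comps)


class TestStackMaps:
    def test_round_trip_through_nifti(self, tmp_path):
        field = small_field(grid=4)
        manifest = write_voxel_field(field, tmp_path)
        panels = stack_maps(manifest, tmp_path / "covariates.tsv")
        # voxel panels equal the generator's stored values (float32 I/O)
        got = np.moveaxis(panels.data, (0, 1), (0, 1))
        present = ~np.isnan(field.data)
        np.testing.assert_allclose(got[present], field.data[present],
                                   rtol=1e-6)
        np.testing.assert_array_equal(np.isnan(got), ~present)

    def test_absent_wave_becomes_missing_outcome(self, tmp_path):
        field = small_field(grid=3)
        manifest_path = write_voxel_field(field, tmp_path)
        import pandas as pd
        man = pd.read_csv(manifest_path, sep="\t")
        dropped = man.iloc[1:]  # remove one subject-wave map
        panels = stack_maps(dropped, tmp_path / "covariates.tsv")
        s, w = man.iloc[0]["subject"], int(man.iloc[0]["wave"])
        i = panels.subjects.index(s)
        assert np.isnan(panels.data[i, w - 1]).all()

    def test_grid_mismatch_names_offending_file(self, tmp_path):
        import nibabel as nib
        import pandas as pd
        field = small_field(grid=3)
        manifest_path = write_voxel_field(field, tmp_path)
        man = pd.read_csv(manifest_path, sep="\t")
        bad = tmp_path / "bad.nii.gz"
        nib.save(nib.Nifti1Image(np.zeros((7, 7, 7), np.float32),
                                 np.eye(4)), bad)
        man.loc[man.index[-1], "path"] = str(bad)
        with pytest.raises(ValueError, match="bad.nii.gz"):
            stack_maps(man, tmp_path / "covariates.tsv")

    def test_unknown_subject_rejected(self, tmp_path):
        import pandas as pd
        field = small_field(grid=3)
        manifest_path = write_voxel_field(field, tmp_path)
        man = pd.read_csv(manifest_path, sep="\t")
        man.loc[man.index[0], "subject"] = "sub-999"
        with pytest.raises(ValueError, match="sub-999"):
            stack_maps(man, tmp_path / "covariates.tsv")


class TestFitVoxelwise:
    def test_deterministic_and_matches_single_fits(self):
        from voxelgrowth.sem import build_lgm_spec, fit_sem
        from voxelgrowth.sem.fit import apply_heywood_rule
        field = small_field(grid=4, seed=5)
        panels = VoxelPanels.from_field(field)
        a = fit_voxelwise(panels, seed=1)
        b = fit_voxelwise(panels, seed=1)
        for k in a.volumes:
            np.testing.assert_array_equal(a[k], b[k])
        # spot-check one voxel against a standalone fit
        spec = build_lgm_spec(3, covariates=("mfq_fof", "age_c"))
        tb = panels.panel((2, 1, 3))
        res = fit_sem(spec, tb, n_starts=1, seed=1, rmsea_interval=False)
        res = apply_heywood_rule(res, spec, tb, n_starts=1, seed=1,
                                 rmsea_interval=False)
        assert a["estimate"][2, 1, 3] == pytest.approx(
            res.estimates["S~mfq_fof"], abs=1e-10)

    def test_worker_count_invariance(self):
        field = small_field(grid=3, seed=7)
        panels = VoxelPanels.from_field(field)
        a = fit_voxelwise(panels, seed=2, n_jobs=1)
        b = fit_voxelwise(panels, seed=2, n_jobs=2)
        for k in a.volumes:
            np.testing.assert_array_equal(a[k], b[k])

    def test_mask_restricts_fits(self):
        field = small_field(grid=4, seed=6)
        mask = np.zeros((4, 4, 4), bool)
        mask[0, 0, 0] = mask[1, 2, 3] = True
        panels = VoxelPanels.from_field(field, mask=mask)
        maps = fit_voxelwise(panels, seed=0)
        assert maps.report["voxels_fit"] == 2
        assert np.isnan(maps["estimate"][3, 3, 3])


class TestQualityMask:
    def _maps(self, rmsea, cfi, srmr, converged=1.0):
        vols = {"rmsea": np.full((1, 1, 1), rmsea),
                "cfi": np.full((1, 1, 1), cfi),
                "srmr": np.full((1, 1, 1), srmr),
                "converged": np.full((1, 1, 1), converged)}
        return StatMapSet(vols, np.eye(4), np.ones((1, 1, 1), bool),
                          "S~m", 0)

    def test_closed_boundary_passes(self):
        assert fit_quality_mask(self._maps(0.10, 0.90, 0.10))[0, 0, 0] == 1

    @pytest.mark.parametrize("rmsea,cfi,srmr", [
        (0.101, 0.95, 0.05), (0.05, 0.89, 0.05), (0.05, 0.95, 0.101)])
    def test_single_criterion_failure(self, rmsea, cfi, srmr):
        assert fit_quality_mask(self._maps(rmsea, cfi, srmr))[0, 0, 0] == 0

    def test_saturated_voxel_passes(self):
        # chi2 = 0: RMSEA 0, CFI 1, SRMR 0
        assert fit_quality_mask(self._maps(0.0, 1.0, 0.0))[0, 0, 0] == 1

    def test_nonconverged_voxel_excluded(self):
        assert fit_quality_mask(self._maps(0.0, 1.0, 0.0, converged=0)) \
            .sum() == 0

    def test_missing_volume_is_error(self):
        maps = self._maps(0, 1, 0)
        del maps.volumes["srmr"]
        with pytest.raises(KeyError, match="srmr"):
            fit_quality_mask(maps)


class TestClusterCorrect:
    def test_single_voxel_below_extent(self):
        p = np.ones((8, 8, 8))
        p[4, 4, 4] = 1e-6
        out = cluster_correct(p, affine=np.diag([2., 2., 2., 1.]))
        assert out == []

    def test_30_voxels_at_2mm_meet_240mm3(self):
        p = np.ones((8, 8, 8))
        p[1, 1:7, 1:6] = 1e-6          # 6 x 5 = 30 voxels, face-connected
        out = cluster_correct(p, affine=np.diag([2., 2., 2., 1.]))
        assert len(out) == 1
        assert out[0].n_voxels == 30
        assert out[0].volume_mm3 == pytest.approx(240.0)

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(0)
        for rep in range(20):
            p = rng.uniform(size=(10, 10, 10))
            out = cluster_correct(p, voxel_p=0.4, min_volume_mm3=0.0,
                                  voxel_volume_mm3=1.0,
                                  connectivity=connectivity)
            got = {frozenset(map(tuple, c.voxels)) for c in out}
            assert got == flood_fill_components(p < 0.4, connectivity)

    def test_quality_mask_intersected(self):
        p = np.full((6, 6, 6), 1e-6)
        qual = np.zeros((6, 6, 6))
        qual[:2] = 1
        out = cluster_correct(p, qual, min_volume_mm3=0.0,
                              voxel_volume_mm3=1.0)
        assert sum(c.n_voxels for c in out) == 72

    def test_reported_clusters_shrink_with_extent_threshold(self):
        """On a fixed null batch, the number of reported clusters is
        non-increasing in the minimum-extent threshold (8/80/240 mm^3)."""
        rng = np.random.default_rng(5)
        affine = np.diag([2., 2., 2., 1.])
        for rep in range(10):
            p = rng.uniform(size=(14, 14, 14))
            counts = [len(cluster_correct(p, voxel_p=0.2, min_volume_mm3=v,
                                          affine=affine))
                      for v in (8.0, 80.0, 240.0)]
            assert counts[0] >= counts[1] >= counts[2]

    def test_unknown_voxel_size_error(self):
        with pytest.raises(ValueError, match="affine"):
            cluster_correct(np.ones((3, 3, 3)))


class TestSelectPeak:
    def _maps(self, est, constrained):
        shape = est.shape
        vols = {"estimate": est,
                "constrained": constrained.astype(float),
                "converged": np.ones(shape)}
        return StatMapSet(vols, np.diag([2., 2., 2., 1.]),
                          np.ones(shape, bool), "S~m", 0)

    def test_single_voxel_cluster(self):
        est = np.zeros((3, 3, 3))
        est[1, 1, 1] = 0.5
        maps = self._maps(est, np.zeros((3, 3, 3), bool))
        c = Cluster(1, np.array([[1, 1, 1]]), 8.0, 1e-5)
        out = select_peak(c, maps)
        assert out.peak_voxel == (1, 1, 1)
        assert out.peak_mm == (2.0, 2.0, 2.0)

    def test_absolute_value_rule(self):
        est = np.zeros((3, 3, 3))
        est[0, 0, 0] = 0.3
        est[0, 0, 1] = -0.4
        maps = self._maps(est, np.zeros((3, 3, 3), bool))
        c = Cluster(1, np.array([[0, 0, 0], [0, 0, 1]]), 16.0, 1e-5)
        assert select_peak(c, maps).peak_voxel == (0, 0, 1)

    def test_constrained_voxels_skipped_and_exhaustive_oracle(self):
        rng = np.random.default_rng(1)
        est = rng.normal(size=(4, 4, 4))
        constrained = rng.uniform(size=(4, 4, 4)) < 0.4
        vox = np.argwhere(np.ones((4, 4, 4), bool))[:30]
        maps = self._maps(est, constrained)
        c = select_peak(Cluster(1, vox, 240.0, 1e-5), maps)
        free = [tuple(v) for v in vox if not constrained[tuple(v)]]
        oracle = max(free, key=lambda v: abs(est[v]))
        assert c.peak_voxel == oracle

    def test_all_constrained_reports_warning(self):
        est = np.ones((2, 2, 2))
        maps = self._maps(est, np.ones((2, 2, 2), bool))
        c = select_peak(Cluster(1, np.array([[0, 0, 0]]), 8.0, 1e-5), maps)
        assert c.peak_voxel is None
        assert any("constraint" in w for w in c.warnings)

    def test_peak_refit_and_slope_variance_range(self):
        field = small_field(grid=4, seed=9)
        panels = VoxelPanels.from_field(field)
        maps = fit_voxelwise(panels, seed=0)
        vox = np.array([[0, 0, 0], [0, 0, 1], [0, 1, 0]])
        c = select_peak(Cluster(1, vox, 24.0, 1e-5), maps, panels=panels)
        if c.peak_voxel is not None:
            assert c.peak_fit is not None
            assert c.slope_var_range[0] <= c.slope_var_range[1]
            tab = cluster_table([c])
            assert tab.loc[0, "n_voxels"] == 3
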