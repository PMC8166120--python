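"""FIML growth-SEM engine: likelihood, moments, fitting, indices, Heywood."""

import dataclasses

import numpy as np
import pytest

from voxelgrowth import AttritionModel, GrowthTruth, SimulationConfig
from voxelgrowth.sem import (LongTable, apply_heywood_rule, baseline_loglik,
                             build_lgm_spec, build_saturated_spec,
                             complete_mvn_loglik, conditional_loglik,
                             covariate_loglik, fiml_loglik, fit_indices,
                             fit_sem, implied_moments, saturated_mvn_em,
                             saturated_loglik)
from voxelgrowth.simulate import generate_cohort, generate_growth_panel

from conftest import RICH_TRUTH


def truth_vector(spec, truth=RICH_TRUTH):
    d = truth.param_dict()
    return np.array([d[n] for n in spec.param_names])


class TestSpecCounting:
    def test_unconditional_three_wave_df(self):
        spec = build_lgm_spec(3)
        # 8 free parameters against 9 outcome moments
        assert spec.n_free == 8
        assert spec.df == 1

    def test_conditional_three_wave_df(self, cond_spec):
        # 12 structural + 5 saturated covariate moments vs 20 joint moments
        assert cond_spec.n_free == 12
        assert cond_spec.n_free_total() == 17
        assert cond_spec.df == 3

    def test_constraint_increases_df(self, cond_spec):
        assert cond_spec.constrain({"S~~S": 0.0}).df == cond_spec.df + 1

    def test_nonzero_first_loading_rejected(self):
        with pytest.raises(ValueError, match="first"):
            build_lgm_spec(3, loadings=(1, 2, 3))

    def test_underidentified_rejected(self):
        from voxelgrowth.sem.spec import Parameter, SemSpec
        # 2 waves, free per-wave residuals: 7 params vs 5 moments
        with pytest.raises(ValueError, match="identified"):
            build_lgm_spec(2)


class TestImpliedMoments:
    def test_deterministic_limit(self):
        spec = build_lgm_spec(3)
        truth = GrowthTruth(alpha_i=0.3, alpha_s=-0.05, psi_ii=0, psi_ss=0,
                            psi_is=0, theta=(0, 0, 0))
        mu, Sigma = implied_moments(spec, truth_vector(spec, truth))
        np.testing.assert_allclose(mu, 0.3 - 0.05 * np.arange(3))
        np.testing.assert_allclose(Sigma, 0.0, atol=1e-15)

    def test_hand_expanded_covariance_algebra(self):
        """Cov(y1, y3) with psi_IS = 0 equals psi_II plus covariate paths."""
        spec = build_lgm_spec(3, covariates=("m",))
        vals = {"I~1": .2, "S~1": -.1, "I~m": .3, "S~m": .15,
                "I~~I": .5, "S~~S": .2, "I~~S": 0.0,
                "y1~~y1": .1, "y2~~y2": .1, "y3~~y3": .1}
        params = np.array([vals[n] for n in spec.param_names])
        mu_x, Sigma_x = np.array([1.5]), np.array([[0.8]])
        mu, Sigma = implied_moments(spec, params, mu_x, Sigma_x)
        # lam1 = (1, 0), lam3 = (1, 2):
        # Cov(y1,y3) = psi_II + (g_I + 0)(g_I + 2 g_S) Var(m)
        expected = .5 + (.3) * (.3 + 2 * .15) * .8
        assert Sigma[0, 2] == pytest.approx(expected, abs=1e-12)
        # mean: mu_y3 = aI + 2 aS + (gI + 2 gS) mu_m
        assert mu[2] == pytest.approx(.2 - .2 + (.3 + .3) * 1.5, abs=1e-12)

    def test_moments_match_monte_carlo(self):
        """Implied moments agree with simulation at n = 200k within MC SE."""
        cfg = SimulationConfig(n_subjects=200000, n_longitudinal=200000,
                               attrition=AttritionModel(retention=(1, 1)))
        recs = generate_cohort(cfg, rng=np.random.default_rng(0))
        panel = generate_growth_panel(recs, RICH_TRUTH, seed=1)
        spec = build_lgm_spec(3, covariates=("mfq_fof", "age_c"))
        mu, Sigma = implied_moments(spec, truth_vector(spec), data=panel)
        V = np.hstack([panel.Y, panel.X])
        n = panel.n
        se_mu = np.sqrt(np.diag(Sigma) / n)
        assert np.all(np.abs(V.mean(axis=0) - mu) < 3.5 * se_mu)
        emp = np.cov(V.T, bias=True)
        se_S = np.sqrt((np.outer(np.diag(Sigma), np.diag(Sigma))
                        + Sigma ** 2) / n)
        assert np.all(np.abs(emp - Sigma) < 3.5 * se_S)


class TestFimlLoglik:
    def test_complete_data_equals_mvn_loglik(self, cond_spec):
        rng = np.random.default_rng(0)
        n = 40
        X = rng.normal(size=(n, 2))
        Y = rng.normal(size=(n, 3)) * 0.2 + 0.3
        data = LongTable(Y, X, x_names=["mfq_fof", "age_c"])
        params = truth_vector(cond_spec)
        ll = fiml_loglik(cond_spec, params, data)
        mu, Sigma = implied_moments(cond_spec, params, data=data)
        direct = complete_mvn_loglik(np.hstack([Y, X]), mu, Sigma)
        assert ll == pytest.approx(direct, abs=1e-8)

    def test_single_wave_subject_contributes_univariate_term(self):
        spec = build_lgm_spec(3)
        params = truth_vector(spec)
        y_full = np.array([[0.1, 0.2, 0.3]])
        y_solo = np.array([[0.1, np.nan, np.nan]])
        ll = conditional_loglik(spec, params, LongTable(y_solo))
        mu, Sigma = implied_moments(spec, params)
        expected = complete_mvn_loglik(np.array([[0.1]]), mu[:1],
                                       Sigma[:1, :1])
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_gradient_matches_central_differences(self, cond_spec,
                                                  small_panel):
        params = truth_vector(cond_spec) * 1.2 + 0.01
        ll, g = conditional_loglik(cond_spec, params, small_panel, grad=True)
        h = 1e-6
        for k in range(len(params)):
            e = np.zeros_like(params)
            e[k] = h
            num = (conditional_loglik(cond_spec, params + e, small_panel)
                   - conditional_loglik(cond_spec, params - e, small_panel)) \
                / (2 * h)
            assert g[k] == pytest.approx(num, rel=1e-4, abs=1e-5)

    def test_gradient_with_structural_paths(self, small_panel):
        from voxelgrowth.parallel import build_parallel_spec, join_panels
        cog = generate_growth_panel(
            generate_cohort(SimulationConfig(seed=7)),
            GrowthTruth(alpha_i=.5, psi_ii=.01, psi_ss=.002, psi_is=0,
                        theta=(.005, .005, .005)), seed=3)
        data = join_panels(small_panel, cog)
        spec = build_parallel_spec()
        rng = np.random.default_rng(1)
        params = spec.start_vector() * 0.1
        # give variances sane positive values
        for i, p in enumerate(spec.free):
            if p.matrix in ("psi", "theta") and p.index[0] == p.index[-1]:
                params[i] = 0.05
        ll, g = conditional_loglik(spec, params, data, grad=True)
        h = 1e-6
        for k in range(len(params)):
            e = np.zeros_like(params)
            e[k] = h
            num = (conditional_loglik(spec, params + e, data)
                   - conditional_loglik(spec, params - e, data)) / (2 * h)
            assert g[k] == pytest.approx(num, rel=1e-4, abs=1e-5)

    def test_nonpsd_returns_minus_inf(self, cond_spec, small_panel):
        params = truth_vector(cond_spec)
        params[cond_spec.param_index("y1~~y1")] = -10.0
        assert conditional_loglik(cond_spec, params, small_panel) == -np.inf


class TestSaturated:
    def test_complete_data_closed_form(self):
        rng = np.random.default_rng(1)
        Y = rng.normal(size=(50, 3))
        X = rng.normal(size=(50, 2))
        data = LongTable(Y, X)
        mu, S, ll, _ = saturated_mvn_em(data)
        V = np.hstack([Y, X])
        mu0 = V.mean(axis=0)
        S0 = np.cov(V.T, bias=True)
        np.testing.assert_allclose(mu, mu0, atol=1e-8)
        np.testing.assert_allclose(S, S0, atol=1e-8)
        assert ll == pytest.approx(complete_mvn_loglik(V, mu0, S0), abs=1e-6)

    def test_em_matches_direct_optimization(self, fixture_panel):
        """EM and quasi-Newton maximization agree on the saturated MLE."""
        ll_em = saturated_loglik(fixture_panel)
        sat = build_saturated_spec(fixture_panel.y_names,
                                   fixture_panel.x_names)
        res = fit_sem(sat, fixture_panel, compute_fit_indices=False,
                      compute_se=False, seed=0)
        assert res.loglik == pytest.approx(ll_em, abs=1e-6)

    def test_monotone_missingness_fixture(self):
        rng = np.random.default_rng(2)
        Y = rng.normal(size=(60, 3))
        Y[20:, 2] = np.nan
        Y[40:, 1] = np.nan
        data = LongTable(Y)
        ll_em = saturated_loglik(data)
        sat = build_saturated_spec(data.y_names, [])
        res = fit_sem(sat, data, compute_fit_indices=False, compute_se=False,
                      seed=0)
        assert res.loglik == pytest.approx(ll_em, abs=1e-6)

    def test_fully_missing_variable_error(self):
        Y = np.column_stack([np.random.default_rng(0).normal(size=10),
                             np.full(10, np.nan), np.ones(10)])
        with pytest.raises(ValueError, match="never observed"):
            saturated_mvn_em(LongTable(Y, np.zeros((10, 1))))


class TestFitLgm:
    def test_recovery_within_three_se(self):
        cfg = SimulationConfig(n_subjects=2000, n_longitudinal=2000,
                               attrition=AttritionModel(retention=(1, 1)))
        recs = generate_cohort(cfg, rng=np.random.default_rng(4))
        panel = generate_growth_panel(recs, RICH_TRUTH, seed=5)
        spec = build_lgm_spec(3, covariates=("mfq_fof", "age_c"))
        res = fit_sem(spec, panel, seed=0)
        tv = truth_vector(spec)
        assert res.converged
        for k, name in enumerate(spec.param_names):
            assert abs(res.estimates[name] - tv[k]) < 3.5 * res.se[name], name

    def test_fiml_equals_complete_ml_when_nothing_missing(self):
        cfg = SimulationConfig(n_subjects=200, n_longitudinal=200,
                               attrition=AttritionModel(retention=(1, 1)))
        recs = generate_cohort(cfg, rng=np.random.default_rng(6))
        panel = generate_growth_panel(recs, RICH_TRUTH, seed=7)
        spec = build_lgm_spec(3, covariates=("mfq_fof", "age_c"))
        res = fit_sem(spec, panel, seed=0, compute_fit_indices=False)
        params = np.array([res.estimates[n] for n in spec.param_names])
        mu, Sigma = implied_moments(spec, params, data=panel)
        direct = complete_mvn_loglik(np.hstack([panel.Y, panel.X]), mu, Sigma)
        assert res.loglik == pytest.approx(direct, abs=1e-6)

    def test_loading_rescale_invariance(self, fixture_panel):
        """Coding waves in months (0, 18, 36) rescales slope quantities by
        1/18 and leaves fit unchanged."""
        s1 = build_lgm_spec(3, covariates=("mfq_fof", "age_c"))
        s18 = build_lgm_spec(3, loadings=(0.0, 18.0, 36.0),
                             covariates=("mfq_fof", "age_c"))
        r1 = fit_sem(s1, fixture_panel, seed=0)
        r18 = fit_sem(s18, fixture_panel, seed=0)
        assert r18.loglik == pytest.approx(r1.loglik, abs=1e-6)
        assert r18.estimates["S~mfq_fof"] * 18 == pytest.approx(
            r1.estimates["S~mfq_fof"], abs=1e-6)
        assert r18.estimates["S~1"] * 18 == pytest.approx(
            r1.estimates["S~1"], abs=1e-6)
        assert r18.estimates["S~~S"] * 18 ** 2 == pytest.approx(
            r1.estimates["S~~S"], abs=1e-6)
        for k in ("chi2", "cfi", "rmsea", "srmr"):
            assert r18.fit.to_dict()[k] == pytest.approx(
                r1.fit.to_dict()[k], abs=1e-5)

    def test_saturated_spec_chi2_zero(self, fixture_panel):
        sat = build_saturated_spec(fixture_panel.y_names,
                                   fixture_panel.x_names)
        res = fit_sem(sat, fixture_panel, seed=0)
        assert res.fit.df == 0
        assert res.fit.chi2 == pytest.approx(0.0, abs=1e-5)
        assert res.fit.cfi == 1.0
        assert res.fit.rmsea == 0.0


class TestFitIndices:
    def test_chi2_below_df_forces_rmsea_zero(self):
        fi = fit_indices(logL_model=-99.0, k_model=17, logL_sat=-100.0,
                         logL_baseline=-150.0, k_baseline=11, N=69,
                         n_moments=20)
        # logL_model above saturated (within tolerance): chi2 clamps to 0 < df
        assert fi.chi2 <= fi.df
        assert fi.rmsea == 0.0

    def test_perfect_fit_block(self):
        fi = fit_indices(logL_model=-100.0, k_model=20, logL_sat=-100.0,
                         logL_baseline=-150.0, k_baseline=11, N=69,
                         n_moments=20, srmr_value=0.0)
        assert fi.df == 0 and fi.cfi == 1.0 and fi.rmsea == 0.0
        assert fi.srmr == 0.0

    def test_cfi_bounds_and_rmsea_ci_order(self, fixture_panel, cond_spec):
        res = fit_sem(cond_spec, fixture_panel, seed=0)
        assert 0.0 <= res.fit.cfi <= 1.0
        lo, hi = res.fit.rmsea_ci
        assert 0.0 <= lo <= res.fit.rmsea <= hi


class TestHeywoodRule:
    def test_no_negative_variance_is_identity(self, fixture_panel, cond_spec):
        res = fit_sem(cond_spec, fixture_panel, seed=0)
        out = apply_heywood_rule(res, cond_spec, fixture_panel, seed=0)
        assert out.constrained_params == []
        assert out.estimates == res.estimates

    def test_boundary_truth_fires_and_never_improves_loglik(self):
        """With a true zero wave-2 residual variance at n = 60, the rule
        fires on a nontrivial fraction of replicates and the refit
        log-likelihood never exceeds the unconstrained one."""
        truth = dataclasses.replace(RICH_TRUTH, theta=(0.02, 0.0, 0.02))
        spec = build_lgm_spec(3, covariates=("mfq_fof", "age_c"))
        cfg = SimulationConfig(n_subjects=60, n_longitudinal=60,
                               attrition=AttritionModel(retention=(1, 1)),
                               truth=truth)
        rng = np.random.default_rng(8)
        recs = generate_cohort(cfg, rng=rng)
        fired = 0
        for r in range(40):
            panel = generate_growth_panel(recs, truth, rng=rng)
            res = fit_sem(spec, panel, seed=0, compute_fit_indices=False)
            if not res.converged:
                continue
            out = apply_heywood_rule(res, spec, panel, seed=0,
                                     compute_fit_indices=False)
            if out.constrained_params:
                fired += 1
                assert out.loglik <= res.loglik + 1e-6
                assert all(out.estimates.get(p, 0.0) == 0.0
                           for p in out.constrained_params
                           if p in out.estimates)
        assert fired >= 8

    def test_slope_disturbance_constrained_like_cognitive_models(self):
        """A negative latent slope disturbance with CI covering 0 is fixed
        to 0 (the working-memory handling), raising df by the number of
        constraints."""
        truth = dataclasses.replace(RICH_TRUTH, psi_ss=0.0, psi_is=0.0)
        spec = build_lgm_spec(3, covariates=("mfq_fof", "age_c"))
        cfg = SimulationConfig(truth=truth)
        rng = np.random.default_rng(9)
        recs = generate_cohort(cfg, rng=rng)
        seen = 0
        for r in range(30):
            panel = generate_growth_panel(recs, truth, rng=rng)
            res = fit_sem(spec, panel, seed=0)
            if not res.converged:
                continue
            out = apply_heywood_rule(res, spec, panel, seed=0)
            if "S~~S" in out.constrained_params:
                seen += 1
                assert out.fit.df == res.fit.df + len(out.constrained_params)
        assert seen >= 3


class TestStandardize:
    def test_unit_variance_construction(self):
        """With all variances ~1 the standardized solution approximates the
        unstandardized one."""
        rng = np.random.default_rng(10)
        n = 3000
        X = rng.standard_normal((n, 2))
        lam = np.column_stack([np.ones(3), np.arange(3.0)])
        eta = X @ np.array([[0.3, 0.0], [0.2, 0.0]]).T \
            + rng.standard_normal((n, 2))
        Y = eta @ lam.T + rng.standard_normal((n, 3))
        panel = LongTable(Y, X, x_names=["mfq_fof", "age_c"])
        spec = build_lgm_spec(3, covariates=("mfq_fof", "age_c"))
        res = fit_sem(spec, panel, seed=0, compute_fit_indices=False)
        # predictor and latent SDs are ~1, so std ~ unstandardized / sd(I)
        got = res.std["I~mfq_fof"]
        g_row = np.array([res.estimates["I~mfq_fof"],
                          res.estimates["I~age_c"]])
        Sx = np.cov(panel.X.T, bias=True)
        lat_sd = np.sqrt(g_row @ Sx @ g_row + res.estimates["I~~I"])
        assert got == pytest.approx(
            res.estimates["I~mfq_fof"] * np.sqrt(Sx[0, 0]) / lat_sd,
            rel=1e-6)
        assert abs(got - 0.3 / np.sqrt(1 + .09)) < 0.05

    def test_zero_path_standardizes_to_zero(self, fixture_panel):
        spec = build_lgm_spec(3, covariates=("mfq_fof", "age_c"),
                              constraints=None)
        res = fit_sem(spec, fixture_panel, seed=0)
        for name, v in res.std.items():
            if res.estimates[name] == 0.0:
                assert v == 0.0


class TestLongTable:
    def test_rejects_incomplete_covariates(self):
        with pytest.raises(ValueError, match="complete"):
            LongTable(np.zeros((3, 3)), np.array([[1.], [np.nan], [0.]]))

    def test_rejects_empty_subjects_without_covariates(self):
        Y = np.array([[1.0, np.nan, np.nan], [np.nan] * 3])
        with pytest.raises(ValueError, match="observed outcome"):
            LongTable(Y)

    def test_pattern_grouping_covers_all_subjects(self, small_panel):
        rows = np.concatenate([r for _, r in small_panel.patterns])
        covered = np.sort(rows)
        expected = np.flatnonzero(small_panel.obs.any(axis=1))
        np.testing.assert_array_equal(covered, expected)
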