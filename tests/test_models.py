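"""Spatial panel ML: transforms, Jacobian, concentrated-likelihood
optima against brute-force oracles, model reductions, reporting."""

import dataclasses

import numpy as np
import pytest
from scipy import optimize

from spatialpanel.models import (
    CollinearityError,
    ModelSpec,
    fit_model,
    fit_ols,
    fit_sdm,
    fit_sem,
    fit_slm,
    log_det_jacobian,
    model_report,
    panel_arrays,
    within_transform,
)
from spatialpanel.simulate import (
    SyntheticConfig,
    simulate_panel,
    slm_recovery_config,
)
from spatialpanel.weights import row_standardize, weights_spectrum

from conftest import binary_weights, random_connected_graph


@pytest.fixture(scope="module")
def slm_panel(china_W):
    cfg = slm_recovery_config(seed=100)
    return simulate_panel(cfg, china_W)


class TestWithinTransform:
    def test_region_constants_annihilated(self):
        N, T = 4, 3
        mu = np.array([1.0, -2.0, 0.5, 3.0])
        y = np.tile(mu, T)
        X = np.ones((N * T, 1))
        yt, _, dof, add_c = within_transform(y, X, N, T, "individual")
        assert np.allclose(yt, 0.0, atol=1e-14)
        assert dof == N and not add_c

    def test_twoway_annihilates_additive_structure(self):
        # y_it = a_i + b_t on a 3x3 toy panel
        a = np.array([1.0, 2.0, -1.0])
        b = np.array([0.5, -0.3, 4.0])
        y = np.concatenate([a + b[t] for t in range(3)])
        X = np.arange(9, dtype=float).reshape(9, 1)
        yt, _, dof, _ = within_transform(y, X, 3, 3, "twoway")
        assert np.allclose(yt, 0.0, atol=1e-13)
        assert dof == 3 + 3 - 1

    def test_pooled_identity_plus_intercept_flag(self):
        y = np.arange(6, dtype=float)
        X = np.arange(12, dtype=float).reshape(6, 2)
        yt, Xt, dof, add_c = within_transform(y, X, 3, 2, "pooled")
        assert np.array_equal(yt, y) and np.array_equal(Xt, X)
        assert dof == 0 and add_c


class TestLogDetJacobian:
    def test_zero_at_rho_zero(self, china_W):
        assert log_det_jacobian(0.0, weights_spectrum(china_W)) == 0.0

    def test_matches_dense_lu_determinant(self):
        rng = np.random.default_rng(17)
        W = row_standardize(binary_weights(random_connected_graph(rng, 6)))
        spec = weights_spectrum(W)
        for rho in (-0.8, -0.3, 0.4, 0.9):
            dense = np.linalg.slogdet(np.eye(6) - rho * W.matrix)
            assert dense[0] > 0
            assert log_det_jacobian(rho, spec) == pytest.approx(
                dense[1], abs=1e-10)

    def test_monotone_divergence_near_one(self, china_W):
        spec = weights_spectrum(china_W)
        vals = [log_det_jacobian(r, spec)
                for r in (0.9, 0.99, 0.999, 0.999999)]
        assert all(b < a for a, b in zip(vals, vals[1:]))
        assert vals[-1] < -10

    def test_domain_error(self, china_W):
        with pytest.raises(ValueError):
            log_det_jacobian(1.5, weights_spectrum(china_W))


class TestConcentratedOptimum:
    def test_slm_matches_grid_search(self, china_W, slm_panel):
        fit = fit_slm(slm_panel, china_W)
        spec = weights_spectrum(china_W)
        lo = 1.0 / spec.min() + 1e-6
        grid = np.linspace(lo, 1 - 1e-6, 2001)
        lls = [fit_slm(slm_panel, china_W, fix_rho=r).log_likelihood
               for r in grid]
        best = grid[int(np.argmax(lls))]
        assert abs(fit.rho[0] - best) <= (grid[1] - grid[0])

    def test_sem_matches_grid_search(self, china_W):
        cfg = SyntheticConfig(family="SEM", lam=0.55, seed=21)
        panel = simulate_panel(cfg, china_W)
        fit = fit_sem(panel, china_W)
        spec = weights_spectrum(china_W)
        lo = 1.0 / spec.min() + 1e-6
        grid = np.linspace(lo, 1 - 1e-6, 2001)
        lls = [fit_sem(panel, china_W, fix_lambda=l).log_likelihood
               for l in grid]
        best = grid[int(np.argmax(lls))]
        assert abs(fit.lam[0] - best) <= (grid[1] - grid[0])

    def test_concentrated_matches_joint_optimization(self, china_W, slm_panel):
        # jointly optimize (beta, rho, log sigma2) of the full likelihood
        # and compare with the profiled optimum
        fit = fit_slm(slm_panel, china_W)
        from spatialpanel import models as m
        y, X, names, N, T = panel_arrays(slm_panel, china_W)
        yt, Xt, _, _ = within_transform(y, X, N, T, "twoway")
        spec_eff = m._effective_spectrum(weights_spectrum(china_W), True)
        Wy = m._blockW(yt, china_W.matrix, N, T, project=True)

        def neg(th):
            return -m._full_ll_lag(th, yt, Xt, Wy, spec_eff, (N - 1) * T, T)

        k = Xt.shape[1]
        b0 = np.linalg.lstsq(Xt, yt, rcond=None)[0]
        s0 = np.var(yt - Xt @ b0)
        th0 = np.concatenate([b0, [0.1, np.log(s0)]])
        res = optimize.minimize(neg, th0, method="Nelder-Mead",
                                options={"maxiter": 20000, "xatol": 1e-8,
                                         "fatol": 1e-10})
        assert res.x[k] == pytest.approx(fit.rho[0], abs=1e-5)

    def test_likelihood_dominance(self, china_W, slm_panel):
        for fitted, fixed in [
            (fit_slm(slm_panel, china_W), fit_slm(slm_panel, china_W, fix_rho=0.0)),
            (fit_sem(slm_panel, china_W), fit_sem(slm_panel, china_W, fix_lambda=0.0)),
            (fit_sdm(slm_panel, china_W), fit_sdm(slm_panel, china_W, fix_rho=0.0)),
        ]:
            assert fitted.log_likelihood >= fixed.log_likelihood


class TestModelReductions:
    @pytest.mark.parametrize("effects", ["individual", "twoway"])
    def test_rho_zero_equals_within_ols(self, china_W, slm_panel, effects):
        spec = ModelSpec(family="SLM", effects=effects)
        fit0 = fit_slm(slm_panel, china_W, spec, fix_rho=0.0)
        y, X, names, N, T = panel_arrays(slm_panel, china_W)
        yt, Xt, _, _ = within_transform(y, X, N, T, effects)
        beta = np.linalg.lstsq(Xt, yt, rcond=None)[0]
        for j, nm in enumerate(names):
            assert fit0.coef(nm) == pytest.approx(beta[j], abs=1e-10)

    def test_lambda_zero_equals_within_ols(self, china_W, slm_panel):
        fit0 = fit_sem(slm_panel, china_W, fix_lambda=0.0)
        y, X, names, N, T = panel_arrays(slm_panel, china_W)
        yt, Xt, _, _ = within_transform(y, X, N, T, "twoway")
        beta = np.linalg.lstsq(Xt, yt, rcond=None)[0]
        for j, nm in enumerate(names):
            assert fit0.coef(nm) == pytest.approx(beta[j], abs=1e-10)

    def test_sem_filtered_regression_self_consistency(self, china_W):
        cfg = SyntheticConfig(family="SEM", lam=0.5912, seed=31)
        panel = simulate_panel(cfg, china_W)
        spec = ModelSpec(family="SEM", effects="individual")
        fit = fit_sem(panel, china_W, spec)
        lam = fit.lam[0]
        y, X, names, N, T = panel_arrays(panel, china_W)
        yt, Xt, _, _ = within_transform(y, X, N, T, "individual")
        Wm = china_W.matrix
        ys = np.concatenate([yt[t*N:(t+1)*N] - lam * Wm @ yt[t*N:(t+1)*N]
                             for t in range(T)])
        Xs = np.vstack([Xt[t*N:(t+1)*N] - lam * Wm @ Xt[t*N:(t+1)*N]
                        for t in range(T)])
        beta = np.linalg.lstsq(Xs, ys, rcond=None)[0]
        for j, nm in enumerate(names):
            assert fit.coef(nm) == pytest.approx(beta[j], abs=1e-10)

    def test_sdm_agrees_with_slm_under_delta_zero_dgp(self, china_W):
        agree = 0
        for seed in range(20):
            cfg = slm_recovery_config(seed=200 + seed)
            panel = simulate_panel(cfg, china_W)
            f_slm = fit_slm(panel, china_W)
            f_sdm = fit_sdm(panel, china_W)
            se1 = abs(f_slm.rho[0] / f_slm.rho[1])
            se2 = abs(f_sdm.rho[0] / f_sdm.rho[1])
            if abs(f_sdm.rho[0] - f_slm.rho[0]) < 2 * np.hypot(se1, se2):
                agree += 1
        assert agree >= 18

    def test_estimates_invariant_to_region_relabeling(self, china_W, slm_panel):
        fit = fit_slm(slm_panel, china_W)
        rng = np.random.default_rng(4)
        perm = rng.permutation(31)
        ids = np.array(china_W.region_order)[perm]
        Wp = row_standardize(binary_weights(
            (china_W.matrix > 0)[np.ix_(perm, perm)] * 1.0))
        Wp.region_order = list(ids)
        fitp = fit_slm(slm_panel, Wp)
        assert fitp.rho[0] == pytest.approx(fit.rho[0], abs=1e-6)
        assert fitp.coef("pm25") == pytest.approx(fit.coef("pm25"), abs=1e-8)


class TestOls:
    def test_exact_fit_recovers_slope(self, china_W):
        rng = np.random.default_rng(2)
        N, T = 31, 5
        x = rng.standard_normal(N * T)
        panel = simulate_panel(SyntheticConfig(seed=2), china_W)
        panel = panel.assign(pm25=x, respdeath=2.0 * x)
        spec = ModelSpec(family="OLS", effects="pooled", covariates=["pm25"])
        fit = fit_ols(panel, china_W, spec)
        assert fit.coef("pm25") == pytest.approx(2.0, abs=1e-10)
        assert fit.coef("const") == pytest.approx(0.0, abs=1e-10)

    def test_ols_biased_under_slm_dgp(self, china_W):
        # omitting the outcome's spatial lag biases the slopes
        bias_ols, bias_slm = [], []
        for seed in range(30):
            cfg = slm_recovery_config(seed=300 + seed)
            panel = simulate_panel(cfg, china_W)
            f_ols = fit_ols(panel, china_W, ModelSpec(family="OLS"))
            f_slm = fit_slm(panel, china_W)
            bias_ols.append(f_ols.coef("pm25") - cfg.beta["pm25"])
            bias_slm.append(f_slm.coef("pm25") - cfg.beta["pm25"])
        assert abs(np.mean(bias_ols)) > abs(np.mean(bias_slm))


class TestDiagnosticsAndReport:
    def test_constant_covariate_collinear_in_sdm(self, china_W):
        panel = simulate_panel(SyntheticConfig(seed=5), china_W)
        panel["flat"] = 1.23
        spec = ModelSpec(family="SDM", effects="pooled",
                         covariates=["pm25", "flat"])
        with pytest.raises(CollinearityError):
            fit_sdm(panel, china_W, spec)

    def test_report_layout_three_models(self, china_W, slm_panel):
        fits = [fit_model(slm_panel, china_W, ModelSpec(family=f))
                for f in ("SDM", "SLM", "SEM")]
        tab = model_report(fits)
        assert {("SDM", "Coef."), ("SLM", "Z"), ("SEM", "p")} <= set(tab.columns)
        assert tab.loc["rho", ("SEM", "Coef.")] is None or \
            np.isnan(tab.loc["rho", ("SEM", "Coef.")])
        assert np.isfinite(tab.loc["lambda", ("SEM", "Coef.")])
        assert np.isfinite(tab.loc["rho", ("SLM", "Coef.")])
        assert "sigma2_e" in tab.index and "R2" in tab.index

    def test_single_ols_report_has_no_spatial_rows(self, china_W, slm_panel):
        tab = model_report([fit_ols(slm_panel, china_W)])
        assert "rho" not in tab.index and "lambda" not in tab.index

    def test_pseudo_r2_in_unit_interval(self, china_W, slm_panel):
        for f in ("SDM", "SLM", "SEM", "OLS"):
            fit = fit_model(slm_panel, china_W, ModelSpec(family=f))
            assert 0.0 <= fit.pseudo_r2 <= 1.0
            assert fit.sigma2_e > 0

    def test_recovered_region_effects_track_truth(self, china_W):
        from spatialpanel.models import recover_effects

        rng = np.random.default_rng(8)
        mu = rng.standard_normal(31)
        cfg = dataclasses.replace(slm_recovery_config(), n_periods=40,
                                  gamma_sd=0.0, seed=9)
        panel = simulate_panel(cfg, china_W, mu=mu)
        spec = ModelSpec(family="SLM", effects="individual")
        fit = fit_slm(panel, china_W, spec)
        eff = recover_effects(fit, panel, china_W)
        got = eff["mu"]
        want = mu - mu.mean()
        assert np.corrcoef(got, want)[0, 1] > 0.99
        assert fit.effects_estimates is eff

    def test_consistency_rmse_shrinks_with_T(self, china_W):
        rmses = []
        for T in (5, 25):
            errs = []
            for seed in range(12):
                cfg = dataclasses.replace(slm_recovery_config(),
                                          n_periods=T, seed=400 + seed)
                panel = simulate_panel(cfg, china_W)
                errs.append(fit_slm(panel, china_W).rho[0] - cfg.rho)
            rmses.append(float(np.sqrt(np.mean(np.square(errs)))))
        assert rmses[1] < rmses[0]
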