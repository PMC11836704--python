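import numpy as np
import pandas as pd
import pytest
from scipy.linalg import cholesky, solve_triangular

from seedsmr._gls import lambda_vcv
from seedsmr.allometry import (
    AllometryFit,
    compare_models,
    fit_ols,
    fit_pgls,
    isometry_test,
    pgls_residuals,
)
from seedsmr.phylo_signal import vcv_from_tree
from seedsmr.simulate import SimulationConfig, simulate_allometric_traits, simulate_tree


def synthetic_xy(tree, rng, b=0.75, lam=0.6, sigma=0.5):
    C = vcv_from_tree(tree).matrix
    h = np.max(np.diag(C))
    x = np.linalg.cholesky(C / h) @ rng.standard_normal(len(C))
    L = np.linalg.cholesky(lambda_vcv(C, lam) / h)
    y = -1.0 + b * x + sigma * (L @ rng.standard_normal(len(C)))
    return x, y


class TestOLS:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        fit = fit_ols(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_matches_closed_form_on_noisy_data(self, rng):
        x = rng.normal(0, 1, 60)
        y = 0.5 + 0.8 * x + rng.normal(0, 0.4, 60)
        fit = fit_ols(x, y)
        # closed-form oracle
        bx = np.cov(x, y)[0, 1] / np.var(x, ddof=1)
        assert fit.slope == pytest.approx(bx, rel=1e-10)
        resid = y - fit.intercept - fit.slope * x
        se = np.sqrt(
            (resid @ resid) / (len(x) - 2) / ((x - x.mean()) ** 2).sum()
        )
        assert fit.se_slope == pytest.approx(se, rel=1e-10)

    def test_residuals_sum_to_zero(self, rng):
        x = rng.normal(0, 1, 40)
        y = x + rng.normal(0, 1, 40)
        fit = fit_ols(x, y)
        assert abs(fit.residuals.sum()) < 1e-9

    def test_slope_coverage_two_se(self, rng):
        hits = 0
        n_rep = 300
        for _ in range(n_rep):
            x = rng.normal(0, 1, 108)
            y = 0.75 * x + rng.normal(0, 0.5, 108)
            fit = fit_ols(x, y)
            if abs(fit.slope - 0.75) <= 2 * fit.se_slope:
                hits += 1
        assert hits / n_rep >= 0.93

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_ols(np.ones(5), np.arange(5.0))
        with pytest.raises(ValueError):
            fit_ols(np.arange(3.0), np.array([1.0, np.nan, 2.0]))


class TestPGLS:
    def test_lambda_zero_equals_ols(self, medium_tree, rng):
        x, y = synthetic_xy(medium_tree, rng)
        ols = fit_ols(x, y)
        pgls = fit_pgls(x, y, medium_tree, lambda_mode="fixed", lam=0.0)
        assert pgls.slope == pytest.approx(ols.slope, abs=1e-8)
        assert pgls.intercept == pytest.approx(ols.intercept, abs=1e-8)

    def test_cholesky_whitening_oracle(self, rng):
        # PGLS with fixed lambda must equal OLS on L^-1-whitened data
        for i in range(10):
            tree = simulate_tree(SimulationConfig(n_species=20), seed=300 + i)
            C = vcv_from_tree(tree).matrix
            x, y = synthetic_xy(tree, rng)
            lam = rng.uniform(0, 1)
            V = lambda_vcv(C, lam)
            L = cholesky(V, lower=True)
            Xw = solve_triangular(L, np.column_stack([np.ones(20), x]), lower=True)
            yw = solve_triangular(L, y, lower=True)
            beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
            fit = fit_pgls(x, y, tree, lambda_mode="fixed", lam=lam)
            assert fit.intercept == pytest.approx(beta[0], abs=1e-8)
            assert fit.slope == pytest.approx(beta[1], abs=1e-8)

    def test_generalized_orthogonality(self, medium_tree, rng):
        x, y = synthetic_xy(medium_tree, rng)
        fit = fit_pgls(x, y, medium_tree)
        C = vcv_from_tree(medium_tree).matrix
        V = lambda_vcv(C, fit.lam)
        X = np.column_stack([np.ones(len(x)), x])
        g = X.T @ np.linalg.solve(V, fit.residuals.to_numpy())
        assert np.all(np.abs(g) < 1e-6)

    def test_ml_lambda_beats_any_fixed_lambda(self, medium_tree, rng):
        x, y = synthetic_xy(medium_tree, rng)
        free = fit_pgls(x, y, medium_tree, reml=False)
        for lam in (0.0, 0.3, 0.7, 1.0):
            fixed = fit_pgls(x, y, medium_tree, lambda_mode="fixed", lam=lam)
            assert free.loglik_ml >= fixed.loglik_ml - 1e-8
            comp = compare_models(fixed, free)
            assert comp["lr"] >= -1e-8

    def test_parameter_recovery_small_grid(self, rng):
        # slope bias of PGLS stays below the OLS slope SE across lambda
        for lam in (0.0, 0.5, 1.0):
            slopes, ses = [], []
            for i in range(15):
                tree = simulate_tree(SimulationConfig(n_species=60), seed=600 + i)
                x, y = synthetic_xy(tree, rng, b=0.75, lam=lam, sigma=0.5)
                fit = fit_pgls(x, y, tree)
                slopes.append(fit.slope)
                ses.append(fit_ols(x, y).se_slope)
            assert abs(np.mean(slopes) - 0.75) < np.mean(ses)

    def test_species_alignment(self, three_taxon_tree):
        lm = pd.Series({"A": 0.0, "B": 1.0, "C": 2.0})
        ls = pd.Series({"A": 0.1, "B": 0.9, "C": 2.2})
        fit = fit_pgls(lm, ls, three_taxon_tree, lambda_mode="fixed", lam=1.0)
        assert list(fit.residuals.index) == three_taxon_tree.taxa

    def test_mismatched_lengths_rejected(self, three_taxon_tree):
        with pytest.raises(ValueError):
            fit_pgls(np.arange(4.0), np.arange(4.0), three_taxon_tree)


class TestIsometry:
    def test_slope_one_gives_t_zero(self):
        fit = AllometryFit(
            method="OLS", intercept=0.0, slope=1.0, se_intercept=0.1,
            se_slope=0.1, t_intercept=0.0, t_slope=10.0, p_slope=0.0,
            df_resid=50, lam=None, loglik_ml=0.0, loglik_reml=0.0,
            n_params=3, r2=0.5, residuals=pd.Series(dtype=float),
            whitened_residuals=None, n=52, sigma2=1.0,
        )
        t, p = isometry_test(fit)
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_arithmetic_from_study_scale_coefficients(self):
        # slope 0.780, SE 0.085, 106 df: |t| = 0.220/0.085 = 2.588, p = 0.011
        fit = AllometryFit(
            method="OLS", intercept=-1.09, slope=0.780, se_intercept=0.094,
            se_slope=0.085, t_intercept=-11.6, t_slope=9.23, p_slope=0.0,
            df_resid=106, lam=None, loglik_ml=0.0, loglik_reml=0.0,
            n_params=3, r2=0.44, residuals=pd.Series(dtype=float),
            whitened_residuals=None, n=108, sigma2=1.0,
        )
        t, p = isometry_test(fit, null_slope=1.0)
        assert t == pytest.approx(2.588, abs=0.005)
        assert p == pytest.approx(0.011, abs=0.001)


class TestModelComparison:
    def test_identical_fits(self, medium_tree, rng):
        x, y = synthetic_xy(medium_tree, rng)
        a = fit_pgls(x, y, medium_tree, lambda_mode="fixed", lam=0.5)
        b = fit_pgls(x, y, medium_tree, lambda_mode="fixed", lam=0.5)
        comp = compare_models(a, b)
        assert comp["delta_aic"] == pytest.approx(0.0, abs=1e-10)
        assert comp["lr"] == pytest.approx(0.0, abs=1e-10)
        assert comp["p"] == 1.0

    def test_chi2_pvalue_for_one_df(self):
        # LR = 3.49 with 1 df corresponds to p ~ 0.062
        from scipy.stats import chi2

        assert chi2.sf(3.49, 1) == pytest.approx(0.0617, abs=1e-3)

    def test_different_n_rejected(self, medium_tree, rng):
        x, y = synthetic_xy(medium_tree, rng)
        a = fit_ols(x, y)
        b = fit_ols(x[:30], y[:30])
        with pytest.raises(ValueError):
            compare_models(a, b)


class TestResiduals:
    def test_collinear_data_zero_residuals(self, medium_tree):
        C = vcv_from_tree(medium_tree).matrix
        x = np.linspace(-1, 2, 50)
        fit = fit_pgls(x, 0.3 + 0.7 * x, medium_tree, lambda_mode="fixed", lam=0.8)
        assert np.all(np.abs(pgls_residuals(fit)) < 1e-9)

    def test_vertical_deviation_definition(self, rng):
        x = rng.normal(0, 1, 30)
        y = 1.0 + 0.5 * x
        y[0] += 0.3  # one species lifted 0.3 above the line
        fit = fit_pgls(
            x, y, _identity_cov(30), lambda_mode="fixed", lam=0.0
        )
        # residual of the lifted species ~ +0.3 (minus the small fit shift)
        assert pgls_residuals(fit).iloc[0] > 0.25

    def test_whitened_residuals_available(self, medium_tree, rng):
        x, y = synthetic_xy(medium_tree, rng)
        fit = fit_pgls(x, y, medium_tree)
        w = pgls_residuals(fit, whitened=True)
        assert len(w) == len(x)
        assert not np.allclose(w, pgls_residuals(fit))


def _identity_cov(n):
    from seedsmr.phylo_signal import PhyloCovariance

    return PhyloCovariance(np.eye(n), [f"s{i}" for i in range(n)])
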