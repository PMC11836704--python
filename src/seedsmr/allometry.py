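"""Metabolic allometry: OLS and PGLS power-law fits of SMR on seed mass.

The allometric model is MR = a * M^b, fitted on log10 scales as
log10(SMR) = log10(a) + b * log10(M).  Two fits are provided:

* ordinary least squares (OLS), appropriate when the predictor is measured
  with much lower relative error than the response, and
* phylogenetic generalized least squares (PGLS), whose error covariance is
  sigma2 * lambda_transform(C, lambda) with C the Brownian shared-path
  matrix; lambda is estimated by REML profile on [0, 1] by default.

Model comparison (AIC, likelihood ratio) re-evaluates both fits at ML so the
likelihoods are comparable; coefficient SEs and t-tests come from the
REML-scaled covariance.  Residuals are ordinary vertical deviations in log10
units (observed minus fitted), not phylogenetically whitened — the whitened
residuals are available separately for diagnostics.

AIC counts the error variance and, when estimated, lambda as parameters and
includes the full Gaussian constant, so absolute AIC values are only
meaningful in differences between models fitted to the same response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, solve_triangular
from scipy.stats import chi2
from scipy.stats import t as t_dist

from ._gls import GLSFit, gls_fit, lambda_vcv, profile_lambda
from .phylo_signal import PhyloCovariance, _align_trait, vcv_from_tree
from .trees import Phylogeny

__all__ = [
    "AllometryFit",
    "fit_ols",
    "fit_pgls",
    "isometry_test",
    "compare_models",
    "pgls_residuals",
]


@dataclass
class AllometryFit:
    """A fitted log-log allometric regression (OLS or PGLS)."""

    method: str  # "OLS" or "PGLS"
    intercept: float  # log10(a)
    slope: float  # scaling exponent b
    se_intercept: float
    se_slope: float
    t_intercept: float
    t_slope: float
    p_slope: float
    df_resid: int
    lam: float | None  # Pagel's lambda (PGLS only)
    loglik_ml: float
    loglik_reml: float | None
    n_params: int  # parameters counted in AIC (coefs + sigma2 [+ lambda])
    r2: float  # adjusted R2 (OLS) or residual R2 (PGLS)
    residuals: pd.Series  # ordinary vertical deviations, log10 units
    whitened_residuals: np.ndarray | None
    n: int
    sigma2: float

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik_ml

    @property
    def coef_a(self) -> float:
        """Power-law intercept a = 10**intercept, in the units of the data."""
        return 10.0 ** self.intercept

    def predict(self, log_mass) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(log_mass, dtype=float)


def _species_index(log_mass) -> pd.Index | None:
    if isinstance(log_mass, pd.Series):
        return log_mass.index
    return None


def fit_ols(log_mass, log_smr) -> AllometryFit:
    """OLS regression of log10 SMR on log10 mass.

    Implemented as PGLS with an identity covariance so the two paths share
    one code base; SEs, t-tests and adjusted R2 follow the usual OLS
    formulas with n - 2 residual df.
    """
    index = _species_index(log_mass)
    x = np.asarray(log_mass, dtype=float)
    y = np.asarray(log_smr, dtype=float)
    if len(x) != len(y):
        raise ValueError("log_mass and log_smr differ in length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 species")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in regression inputs")
    if np.ptp(x) == 0:
        raise ValueError("zero predictor variance")
    X = np.column_stack([np.ones(n), x])
    fit = gls_fit(y, X, np.eye(n))
    sigma2 = fit.sigma2_reml  # = SSE / (n - 2)
    se = np.sqrt(sigma2 * np.diag(fit.cov_unscaled))
    tvals = fit.beta / se
    df = n - 2
    sse = fit.quad
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / df
    resid = pd.Series(fit.resid, index=index) if index is not None else pd.Series(fit.resid)
    return AllometryFit(
        method="OLS",
        intercept=float(fit.beta[0]),
        slope=float(fit.beta[1]),
        se_intercept=float(se[0]),
        se_slope=float(se[1]),
        t_intercept=float(tvals[0]),
        t_slope=float(tvals[1]),
        p_slope=2.0 * float(t_dist.sf(abs(tvals[1]), df)),
        df_resid=df,
        lam=None,
        loglik_ml=fit.loglik_ml,
        loglik_reml=fit.loglik_reml,
        n_params=3,  # intercept, slope, sigma2
        r2=float(adj_r2),
        residuals=resid,
        whitened_residuals=fit.resid.copy(),
        n=n,
        sigma2=float(sigma2),
    )


def fit_pgls(
    log_mass,
    log_smr,
    tree: Phylogeny | PhyloCovariance,
    lambda_mode: str = "ML",
    lam: float | None = None,
    reml: bool = True,
) -> AllometryFit:
    """PGLS regression of log10 SMR on log10 mass with Pagel's lambda.

    ``lambda_mode='ML'`` profiles lambda on [0, 1] (REML by default, per
    ``reml``); ``lambda_mode='fixed'`` uses the supplied ``lam``.  The
    residual R2 is 1 - SSE_gls / SSE_null with the null being the
    phylogenetic mean-only model under the same covariance.
    """
    cov = tree if isinstance(tree, PhyloCovariance) else vcv_from_tree(tree)
    C = cov.matrix
    if isinstance(log_mass, (pd.Series, dict)):
        x = _align_trait(log_mass, cov.taxa)
        y = _align_trait(log_smr, cov.taxa)
        index = pd.Index(cov.taxa)
    else:
        x = np.asarray(log_mass, dtype=float)
        y = np.asarray(log_smr, dtype=float)
        index = None
        if len(x) != C.shape[0]:
            raise ValueError("trait length does not match tree size")
    n = len(x)
    X = np.column_stack([np.ones(n), x])

    estimated_lambda = False
    if lambda_mode.upper() == "ML":
        lam_hat, fit = profile_lambda(y, X, C, criterion="reml" if reml else "ml")
        estimated_lambda = True
    elif lambda_mode == "fixed":
        if lam is None:
            raise ValueError("lambda_mode='fixed' requires lam")
        lam_hat = float(lam)
        fit = gls_fit(y, X, lambda_vcv(C, lam_hat))
    else:
        raise ValueError("lambda_mode must be 'ML' or 'fixed'")

    V = lambda_vcv(C, lam_hat)
    sigma2 = fit.sigma2_reml
    se = np.sqrt(sigma2 * np.diag(fit.cov_unscaled))
    tvals = fit.beta / se
    df = n - 2

    null = gls_fit(y, np.ones((n, 1)), V)
    r2_resid = 1.0 - fit.quad / null.quad

    L = cholesky(V, lower=True)
    whitened = solve_triangular(L, fit.resid, lower=True)
    resid = pd.Series(fit.resid, index=index) if index is not None else pd.Series(fit.resid)
    return AllometryFit(
        method="PGLS",
        intercept=float(fit.beta[0]),
        slope=float(fit.beta[1]),
        se_intercept=float(se[0]),
        se_slope=float(se[1]),
        t_intercept=float(tvals[0]),
        t_slope=float(tvals[1]),
        p_slope=2.0 * float(t_dist.sf(abs(tvals[1]), df)),
        df_resid=df,
        lam=lam_hat,
        loglik_ml=fit.loglik_ml,
        loglik_reml=fit.loglik_reml,
        n_params=3 + (1 if estimated_lambda else 0),
        r2=float(r2_resid),
        residuals=resid,
        whitened_residuals=whitened,
        n=n,
        sigma2=float(sigma2),
    )


def isometry_test(fit: AllometryFit, null_slope: float = 1.0) -> tuple[float, float]:
    """Single-sample t-test of the fitted slope against a null (isometry = 1).

    Returns (|t|, two-sided p) with n - 2 residual df.
    """
    if fit.se_slope <= 0:
        raise ValueError("slope SE must be positive")
    t = abs(null_slope - fit.slope) / fit.se_slope
    p = 2.0 * float(t_dist.sf(t, fit.df_resid))
    return float(t), p


def compare_models(fit_a: AllometryFit, fit_b: AllometryFit) -> dict:
    """AIC and likelihood-ratio comparison of two fits to the same response.

    Uses ML log-likelihoods (REML values are not comparable across mean
    structures).  The LR statistic is 2*(ll_b - ll_a) with df equal to the
    parameter-count difference; with df = 0 (non-nested same-size models) no
    p-value is produced.
    """
    if fit_a.n != fit_b.n:
        raise ValueError("fits have different n; responses are not comparable")
    delta_aic = fit_a.aic - fit_b.aic
    lr = 2.0 * (fit_b.loglik_ml - fit_a.loglik_ml)
    df = abs(fit_b.n_params - fit_a.n_params)
    if df > 0:
        p = float(chi2.sf(max(lr if fit_b.n_params > fit_a.n_params else -lr, 0.0), df))
    else:
        p = 1.0 if lr == 0 else float("nan")
    return {"delta_aic": float(delta_aic), "lr": float(lr), "df": int(df), "p": p}


def pgls_residuals(fit: AllometryFit, whitened: bool = False) -> pd.Series:
    """Per-species residuals of a fit.

    Default: ordinary vertical deviations in log10 units (observed minus the
    fitted allometric line) — the quantity carried into the correlate
    analyses.  ``whitened=True`` returns L^-1 e (decorrelated scale) for
    model diagnostics.
    """
    if whitened:
        if fit.whitened_residuals is None:
            raise ValueError("whitened residuals unavailable for this fit")
        return pd.Series(fit.whitened_residuals, index=fit.residuals.index)
    return fit.residuals
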