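"""Internal generalized-least-squares machinery shared by the signal and
allometry modules: Pagel-lambda covariance transforms, profiled Gaussian
log-likelihoods (ML and REML) and bounded lambda optimization on [0, 1]."""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve
from scipy.optimize import minimize_scalar

LOG2PI = np.log(2.0 * np.pi)


class SingularCovarianceError(np.linalg.LinAlgError):
    pass


def lambda_vcv(C: np.ndarray, lam: float) -> np.ndarray:
    """Pagel transform: multiply off-diagonal entries by lam, keep diagonal."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    return V


class GLSFit(NamedTuple):
    beta: np.ndarray  # GLS coefficients
    cov_unscaled: np.ndarray  # (X' V^-1 X)^-1
    resid: np.ndarray  # ordinary (response-scale) residuals y - X beta
    quad: float  # e' V^-1 e
    logdet_v: float
    logdet_xvx: float
    n: int
    p: int

    @property
    def sigma2_ml(self) -> float:
        return self.quad / self.n

    @property
    def sigma2_reml(self) -> float:
        return self.quad / (self.n - self.p)

    @property
    def loglik_ml(self) -> float:
        n = self.n
        return -0.5 * (n * (LOG2PI + np.log(self.sigma2_ml) + 1.0) + self.logdet_v)

    @property
    def loglik_reml(self) -> float:
        n, p = self.n, self.p
        return -0.5 * (
            (n - p) * (LOG2PI + np.log(self.sigma2_reml) + 1.0)
            + self.logdet_v
            + self.logdet_xvx
        )


def gls_fit(y: np.ndarray, X: np.ndarray, V: np.ndarray) -> GLSFit:
    """Exact GLS via Cholesky of V; raises on singular covariance."""
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    n, p = X.shape
    try:
        cf = cho_factor(V, lower=True)
    except LinAlgError as exc:
        raise SingularCovarianceError(
            "phylogenetic covariance matrix is singular (identical tips or "
            "zero-length terminal structure?)"
        ) from exc
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    Vi_X = cho_solve(cf, X)
    Vi_y = cho_solve(cf, y)
    xvx = X.T @ Vi_X
    try:
        cov_unscaled = np.linalg.inv(xvx)
    except LinAlgError as exc:
        raise SingularCovarianceError("X' V^-1 X is singular") from exc
    beta = cov_unscaled @ (X.T @ Vi_y)
    resid = y - X @ beta
    quad = float(resid @ cho_solve(cf, resid))
    sign, logdet_xvx = np.linalg.slogdet(xvx)
    return GLSFit(
        beta=beta,
        cov_unscaled=cov_unscaled,
        resid=resid,
        quad=max(quad, 1e-300),
        logdet_v=logdet_v,
        logdet_xvx=float(logdet_xvx),
        n=n,
        p=p,
    )


def profile_lambda(
    y: np.ndarray,
    X: np.ndarray,
    C: np.ndarray,
    criterion: str = "ml",
    xatol: float = 1e-6,
) -> tuple[float, GLSFit]:
    """Maximize the profiled ML or REML likelihood over lambda in [0, 1].

    Bounded scalar optimization; the interior optimum is compared against
    both boundary values so ties at 0 or 1 are reported as boundary values.
    """
    if criterion not in ("ml", "reml"):
        raise ValueError("criterion must be 'ml' or 'reml'")

    def ll(lam: float) -> float:
        fit = gls_fit(y, X, lambda_vcv(C, lam))
        return fit.loglik_ml if criterion == "ml" else fit.loglik_reml

    res = minimize_scalar(
        lambda lam: -ll(lam), bounds=(0.0, 1.0), method="bounded",
        options={"xatol": xatol},
    )
    candidates = [0.0, 1.0, float(res.x)]
    values = [ll(c) for c in candidates]
    best = int(np.argmax(values))
    lam_hat = candidates[best]
    return lam_hat, gls_fit(y, X, lambda_vcv(C, lam_hat))
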