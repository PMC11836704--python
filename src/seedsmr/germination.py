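"""Germination kinetics: log-logistic time-course fits, Gmax and T50.

Cumulative germination over time is sigmoidal on a log time axis and is
modelled with the three-parameter log-logistic curve

    f(t) = d / (1 + exp(b * (ln t - ln e)))

with upper asymptote d (% germination), inflection time e (days) and
dimensionless slope b (negative for an increasing curve).  T50 — the time to
half of the *fitted maximum* germination — equals e under this
parameterization (a relative ED50: when d < 100 this is not the time to 50%
of sown seeds).  Gmax is the final germination percentage among viable seeds,
with cut-test-dead seeds removed from the denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "GerminationCurve",
    "GerminationFitError",
    "log_logistic",
    "fit_log_logistic",
    "compute_gmax",
]


class GerminationFitError(ValueError):
    pass


@dataclass
class GerminationCurve:
    b: float  # slope parameter (dimensionless, < 0 for increasing curves)
    d: float  # upper asymptote, % germination, in (0, 100]
    e: float  # inflection time, days
    t50: float  # time to d/2, days (== e for this parameterization)
    gmax: float  # maximum observed cumulative germination, %
    converged: bool

    def predict(self, times) -> np.ndarray:
        return log_logistic(np.asarray(times, dtype=float), self.b, self.d, self.e)


def log_logistic(t, b, d, e):
    """Three-parameter log-logistic curve d / (1 + exp(b (ln t - ln e)))."""
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore"):
        logt = np.where(t > 0, np.log(np.maximum(t, 1e-300)), -np.inf)
    z = b * (logt - np.log(e))
    # guard overflow in exp for extreme z
    z = np.clip(z, -700, 700)
    return d / (1.0 + np.exp(z))


def fit_log_logistic(times, cum_germ_pct) -> GerminationCurve:
    """Least-squares fit of the three-parameter log-logistic curve.

    times: observation times (days), >= 4 points; cum_germ_pct: cumulative
    germination percentages, expected non-decreasing (a warning is issued
    otherwise and the fit proceeds — scoring noise can produce small dips).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(cum_germ_pct, dtype=float)
    if len(t) != len(y):
        raise ValueError("times and cum_germ_pct differ in length")
    if len(t) < 4:
        raise GerminationFitError("need at least 4 time points")
    if np.all(y <= 0):
        raise GerminationFitError("no germination observed; curve undefined")
    if np.any(np.diff(y) < 0):
        warnings.warn("cumulative germination is not non-decreasing", stacklevel=2)

    gmax = float(y.max())
    d0 = gmax
    # start e at the observation time nearest half the observed maximum
    e0 = float(t[np.argmin(np.abs(y - d0 / 2.0))])
    e0 = max(e0, float(t[t > 0].min()) if np.any(t > 0) else 1.0)
    p0 = [-2.0, d0, e0]
    bounds = ([-50.0, 1e-6, 1e-6], [-1e-8, 100.0, np.inf])
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                log_logistic, t, y, p0=p0, bounds=bounds, maxfev=20000
            )
    except RuntimeError:
        converged = False
        popt = p0
    b, d, e = (float(v) for v in popt)
    return GerminationCurve(b=b, d=d, e=e, t50=e, gmax=gmax, converged=converged)


def compute_gmax(n_germinated: int, n_sown: int, n_dead: int = 0) -> float:
    """Final germination percentage of viable seeds.

    Seeds scored dead by cut-test are removed from the denominator:
    gmax = 100 * germinated / (sown - dead).
    """
    n_viable = n_sown - n_dead
    if n_viable <= 0:
        raise GerminationFitError("no viable seeds; Gmax undefined")
    if not 0 <= n_germinated <= n_viable:
        raise ValueError("n_germinated must be between 0 and the viable count")
    return 100.0 * n_germinated / n_viable
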