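"""Correlates of SMR residuals: regressions, group tests and model selection.

The PGLS residuals (log10 vertical deviations of SMR from the allometric
line) are screened against germination traits, domestication status, an
ordered climate-class gradient and a 15-variable bioclim panel:

* univariate linear regressions (Gmax, T50, crop-vs-wild indicator),
* Welch's unequal-variance t for direct group comparisons of traits,
* one-way ANOVA over Koeppen-Geiger climate classes, plus a single-df
  a-priori contrast for the monotone aridity trend over the ordered classes,
* backward stepwise multiple regression over the bioclim panel with
  type-III F statistics (for single-df continuous terms without
  interactions, the type-III F equals the squared coefficient t).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RegressionResult",
    "StepwiseResult",
    "simple_regression",
    "welch_t",
    "climate_anova",
    "ordered_contrast",
    "backward_stepwise",
]


@dataclass
class RegressionResult:
    slope: float
    se: float
    intercept: float
    f: float
    df1: int
    df2: int
    p: float
    n: int


@dataclass
class StepwiseResult:
    """Backward-elimination outcome over the bioclim panel."""

    retained: pd.DataFrame  # term, slope, se, F, df1, df2, p
    dropped: list[str]  # removal order
    n: int
    condition_number: float


def _pair_finite(y, x) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(y) != len(x):
        raise ValueError("inputs differ in length")
    ok = np.isfinite(y) & np.isfinite(x)
    return y[ok], x[ok]


def simple_regression(residuals, covariate) -> RegressionResult:
    """Univariate OLS of residuals on one covariate, reported with F = t^2.

    Binary factors (e.g. a 0/1 crop indicator) are passed as the covariate,
    in which case the slope is the group-mean difference.  Incomplete pairs
    are dropped.
    """
    y, x = _pair_finite(residuals, covariate)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    t = float(res.tvalues[1])
    return RegressionResult(
        slope=float(res.params[1]),
        se=float(res.bse[1]),
        intercept=float(res.params[0]),
        f=t * t,
        df1=1,
        df2=int(res.df_resid),
        p=float(res.pvalues[1]),
        n=n,
    )


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test with Satterthwaite df.

    Returns (t, df, two-sided p).  Chosen over the pooled test because group
    variances of germination traits differ strongly between crop and wild
    species.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("zero variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def _grouped(residuals, labels, min_group_n: int = 2):
    df = pd.DataFrame({"y": np.asarray(residuals, dtype=float), "g": list(labels)})
    df = df.dropna()
    counts = df["g"].value_counts()
    keep = counts.index[counts >= min_group_n]
    dropped = sorted(set(counts.index) - set(keep))
    return df[df["g"].isin(keep)], dropped


def climate_anova(
    residuals, climate_class, min_group_n: int = 2
) -> tuple[float, int, int, float]:
    """One-way ANOVA of residuals over climate classes.

    Classes with fewer than ``min_group_n`` species are removed first (a
    singleton class contributes no within-group variance).  Returns
    (F, df_between, df_within, p).
    """
    df, _ = _grouped(residuals, climate_class, min_group_n)
    groups = [g["y"].to_numpy() for _, g in df.groupby("g")]
    if len(groups) < 2:
        raise ValueError("need at least 2 non-singleton groups")
    f, p = stats.f_oneway(*groups)
    df1 = len(groups) - 1
    df2 = len(df) - len(groups)
    return float(f), df1, df2, float(p)


def ordered_contrast(
    residuals,
    climate_class,
    ordered_levels,
    scheme: str = "linear",
    min_group_n: int = 2,
) -> tuple[float, int, float]:
    """Single-df a-priori contrast for a monotone trend over ordered groups.

    ``ordered_levels`` ranks the classes (e.g. by increasing aridity:
    Csa < BSh < BWh).  The default 'linear' scheme uses centred equally
    spaced coefficients (-1, 0, +1 for three groups) on the group means with
    the pooled ANOVA error term:

        F = (sum c_i ybar_i)^2 / (MSE * sum c_i^2 / n_i),  df = (1, N - k).

    ``scheme='successive'`` instead tests the first forward difference
    between consecutive levels averaged over steps.  Returns (F, df2, p).
    """
    df, _ = _grouped(residuals, climate_class, min_group_n)
    levels = [l for l in ordered_levels if l in set(df["g"])]
    k = len(levels)
    if k < 3:
        raise ValueError("need at least 3 ordered groups present in the data")
    means = np.array([df.loc[df["g"] == l, "y"].mean() for l in levels])
    ns = np.array([(df["g"] == l).sum() for l in levels])
    if scheme == "linear":
        c = np.arange(k, dtype=float) - (k - 1) / 2.0
    elif scheme == "successive":
        c = np.zeros(k)
        c[0], c[-1] = -1.0, 1.0
    else:
        raise ValueError("scheme must be 'linear' or 'successive'")
    c = c / np.sqrt((c**2).sum())
    sse = sum(
        ((df.loc[df["g"] == l, "y"] - m) ** 2).sum() for l, m in zip(levels, means)
    )
    n_total = int(ns.sum())
    df2 = n_total - k
    mse = sse / df2
    L = float(c @ means)
    var_l = mse * float((c**2 / ns).sum())
    f = L * L / var_l
    p = float(stats.f.sf(f, 1, df2))
    return float(f), df2, p


def backward_stepwise(
    residuals,
    covariates: pd.DataFrame,
    alpha_stay: float = 0.05,
) -> StepwiseResult:
    """Backward elimination over a covariate panel by type-III p-values.

    Starting from the full additive model (no interactions), the single term
    with the largest p-value above ``alpha_stay`` is removed and the model
    refitted, until every retained term satisfies p <= alpha_stay.  Ties are
    broken alphabetically by variable name.  Collinear covariates are kept
    in the model (they can carry distinct effects despite correlation); the
    design must still be full rank, and the condition number of the
    standardized design is reported.
    """
    y = np.asarray(residuals, dtype=float)
    X = covariates.copy()
    if len(y) != len(X):
        raise ValueError("residuals and covariates differ in length")
    ok = np.isfinite(y) & np.isfinite(X.to_numpy(dtype=float)).all(axis=1)
    y = y[ok]
    X = X.loc[ok]
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"n = {n} too small for {p} covariates plus intercept")
    rank = np.linalg.matrix_rank(sm.add_constant(X.to_numpy(dtype=float)))
    if rank < p + 1:
        corr = X.corr().abs()
        aliased = sorted(
            {
                tuple(sorted((a, b)))
                for a in corr.columns
                for b in corr.columns
                if a != b and corr.loc[a, b] > 1 - 1e-10
            }
        )
        raise ValueError(f"singular design; aliased columns: {aliased}")
    Z = (X - X.mean()) / X.std(ddof=1)
    cond = float(np.linalg.cond(sm.add_constant(Z.to_numpy(dtype=float))))

    dropped: list[str] = []
    terms = list(X.columns)
    while terms:
        res = sm.OLS(y, sm.add_constant(X[terms])).fit()
        pvals = res.pvalues.drop("const")
        worst_p = pvals.max()
        if worst_p <= alpha_stay:
            break
        # largest p; alphabetical tie-break
        candidates = sorted(pvals.index[pvals == worst_p])
        victim = candidates[0]
        terms.remove(victim)
        dropped.append(victim)
    if terms:
        res = sm.OLS(y, sm.add_constant(X[terms])).fit()
        tvals = res.tvalues.drop("const")
        retained = pd.DataFrame(
            {
                "term": terms,
                "slope": res.params.drop("const").to_numpy(),
                "se": res.bse.drop("const").to_numpy(),
                "F": (tvals**2).to_numpy(),
                "df1": 1,
                "df2": int(res.df_resid),
                "p": res.pvalues.drop("const").to_numpy(),
            }
        )
    else:
        retained = pd.DataFrame(
            columns=["term", "slope", "se", "F", "df1", "df2", "p"]
        )
    return StepwiseResult(
        retained=retained, dropped=dropped, n=n, condition_number=cond
    )
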