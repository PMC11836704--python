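"""Phylogenetic signal: Brownian covariance, Pagel's lambda, Blomberg's K.

Under Brownian motion (BM) on a rooted tree, trait covariance between two
tips is proportional to the shared root-to-MRCA path length.  Pagel's lambda
scales the off-diagonal (shared-history) part of that matrix: lambda = 0 is
phylogenetic independence, lambda = 1 full BM.  Blomberg's K compares the
observed ratio of among-species variance to phylogenetically corrected
variance against its BM expectation (K = 1 under BM); its significance comes
from random tip-label permutations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import chi2

from ._gls import SingularCovarianceError, gls_fit, lambda_vcv, profile_lambda
from .trees import Phylogeny

__all__ = [
    "PhyloCovariance",
    "LambdaStats",
    "KStats",
    "SignalStats",
    "vcv_from_tree",
    "lambda_transform",
    "pagel_lambda_ml",
    "blomberg_k",
    "phylo_signal",
]


@dataclass
class PhyloCovariance:
    """n x n shared-path-length matrix (Myr) with its taxon order."""

    matrix: np.ndarray
    taxa: list[str]

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.taxa):
            raise ValueError("matrix shape does not match taxa")
        self.matrix = m


def vcv_from_tree(phylogeny: Phylogeny) -> PhyloCovariance:
    """Brownian-motion covariance: C[i, j] = root-to-MRCA(i, j) path length.

    The diagonal holds root-to-tip depths.  Taxon order matches
    ``phylogeny.taxa`` (leaf order).
    """
    tree = phylogeny.tree
    index = {label: i for i, label in enumerate(phylogeny.taxa)}
    n = len(index)
    C = np.zeros((n, n))
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        length = node.edge.length or 0.0
        if length < 0:
            raise ValueError("negative branch length in tree")
        node._depth = (0.0 if parent is None else parent._depth) + (
            length if parent is not None else 0.0
        )
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            C[i, i] = node._depth
            node._tipset = [i]
        else:
            child_sets = [c._tipset for c in node.child_nodes()]
            for sa, sb in combinations(child_sets, 2):
                for i in sa:
                    for j in sb:
                        C[i, j] = C[j, i] = node._depth
            node._tipset = [i for s in child_sets for i in s]
    return PhyloCovariance(matrix=C, taxa=list(phylogeny.taxa))


def lambda_transform(cov: PhyloCovariance | np.ndarray, lam: float):
    """Pagel transform: off-diagonals scaled by lam, diagonal unchanged."""
    if isinstance(cov, PhyloCovariance):
        return PhyloCovariance(lambda_vcv(cov.matrix, lam), list(cov.taxa))
    return lambda_vcv(np.asarray(cov, dtype=float), lam)


def _align_trait(trait, taxa: list[str]) -> np.ndarray:
    """Order a species-keyed trait (Series/dict) or array to the taxon order."""
    if isinstance(trait, pd.Series):
        trait = trait.to_dict()
    if isinstance(trait, dict):
        missing = [t for t in taxa if t not in trait]
        if missing:
            raise ValueError(f"trait missing for tips: {missing[:5]}")
        return np.array([float(trait[t]) for t in taxa])
    arr = np.asarray(trait, dtype=float)
    if len(arr) != len(taxa):
        raise ValueError("trait length does not match number of tips")
    return arr


@dataclass
class LambdaStats:
    """Pagel's lambda ML estimate with boundary likelihood-ratio tests.

    p-values use the 50:50 chi2_0 : chi2_1 boundary mixture; both the test
    against lambda = 0 (no signal) and against lambda = 1 (pure BM) are
    reported.
    """

    lambda_hat: float
    loglik: float
    loglik_lambda0: float
    loglik_lambda1: float
    p_vs_zero: float
    p_vs_one: float


@dataclass
class KStats:
    k: float
    p: float
    n_perm: int


@dataclass
class SignalStats:
    trait: str
    lam: LambdaStats
    k: KStats

    def to_dict(self) -> dict:
        return {
            "trait": self.trait,
            "lambda": self.lam.lambda_hat,
            "lambda_loglik": self.lam.loglik,
            "lambda_p_vs_zero": self.lam.p_vs_zero,
            "lambda_p_vs_one": self.lam.p_vs_one,
            "K": self.k.k,
            "K_p": self.k.p,
        }


def _boundary_lrt_p(ll_full: float, ll_null: float) -> float:
    lr = 2.0 * (ll_full - ll_null)
    if lr <= 0:
        return 1.0
    return 0.5 * float(chi2.sf(lr, df=1))


def pagel_lambda_ml(
    trait, tree: Phylogeny | PhyloCovariance, xatol: float = 1e-6
) -> LambdaStats:
    """Maximum-likelihood Pagel's lambda for one trait.

    The trait is modelled as multivariate normal with mean mu * 1 and
    covariance sigma2 * lambda_transform(C, lambda); mu and sigma2 are
    profiled out analytically and lambda maximized on [0, 1].
    """
    cov = tree if isinstance(tree, PhyloCovariance) else vcv_from_tree(tree)
    y = _align_trait(trait, cov.taxa)
    if np.ptp(y) == 0:
        raise ValueError("trait has zero variance; lambda undefined")
    n = len(y)
    X = np.ones((n, 1))
    C = cov.matrix
    lam_hat, fit = profile_lambda(y, X, C, criterion="ml", xatol=xatol)
    ll0 = gls_fit(y, X, lambda_vcv(C, 0.0)).loglik_ml
    ll1 = gls_fit(y, X, lambda_vcv(C, 1.0)).loglik_ml
    return LambdaStats(
        lambda_hat=lam_hat,
        loglik=fit.loglik_ml,
        loglik_lambda0=ll0,
        loglik_lambda1=ll1,
        p_vs_zero=_boundary_lrt_p(fit.loglik_ml, ll0),
        p_vs_one=_boundary_lrt_p(fit.loglik_ml, ll1),
    )


def blomberg_k(
    trait,
    tree: Phylogeny | PhyloCovariance,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> KStats:
    """Blomberg's K with a tip-permutation significance test.

    K = (MSE0/MSE)_observed / [(tr(C) - n / sum(C^-1)) / (n - 1)], where MSE0
    is the mean squared deviation of the trait from its phylogenetically
    corrected mean and MSE the GLS mean squared error under C.  The one-sided
    p-value counts random tip-label permutations whose MSE0/MSE ratio is at
    least the observed one, with add-one smoothing.
    """
    cov = tree if isinstance(tree, PhyloCovariance) else vcv_from_tree(tree)
    C = cov.matrix
    y = _align_trait(trait, cov.taxa)
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 tips for Blomberg's K")
    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError as exc:
        raise SingularCovarianceError(
            "covariance matrix singular; check for duplicated tips or "
            "zero-length branches"
        ) from exc
    ones = np.ones(n)
    w = Cinv @ ones
    denom_a = ones @ w

    def ratio(vec: np.ndarray) -> float:
        a = (w @ vec) / denom_a
        d = vec - a
        mse0 = d @ d
        mse = d @ (Cinv @ d)
        return mse0 / mse

    observed = ratio(y)
    expected = (np.trace(C) - n / denom_a) / (n - 1)
    k = observed / expected

    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    exceed = 0
    for _ in range(n_perm):
        if ratio(rng.permutation(y)) >= observed:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return KStats(k=float(k), p=float(p), n_perm=n_perm)


def phylo_signal(
    trait,
    tree: Phylogeny | PhyloCovariance,
    trait_name: str = "trait",
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> SignalStats:
    """Convenience wrapper computing both lambda and K for one trait."""
    cov = tree if isinstance(tree, PhyloCovariance) else vcv_from_tree(tree)
    return SignalStats(
        trait=trait_name,
        lam=pagel_lambda_ml(trait, cov),
        k=blomberg_k(trait, cov, n_perm=n_perm, seed=seed),
    )
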