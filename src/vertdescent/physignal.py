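"""Phylogenetic signal: Blomberg's K and its multivariate extension K_mult.

Blomberg's K compares the observed ratio of tip variance around the
phylogenetic (GLS) mean to the variance of phylogenetically corrected
residuals, against the same ratio expected under Brownian motion on the
tree:

    K = [MSE0 / MSE] / [(tr C - n / sum(C^-1)) / (n - 1)]

with C the phylogenetic VCV, MSE0 = (x - a)'(x - a)/(n - 1),
MSE = (x - a)' C^-1 (x - a)/(n - 1), and a the GLS estimate of the root
state. K has expectation ~1 under Brownian motion, and falls toward 0
for traits that are independent of the phylogeny.

K_mult replaces the sums of squares by Frobenius norms of the trait
matrix (rows = species), optionally after a PCA reduction keeping the
smallest leading set of components whose cumulative explained variance
reaches a threshold; with one trait it equals Blomberg's K exactly.

Significance comes from tip-label permutations: p = (b + 1)/(B + 1)
where b counts permuted statistics >= the observed one; the effect size
is the observed statistic standardized by the permutation distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import dendropy
from scipy import linalg

from .phylo import phylo_vcv

__all__ = ["SignalResult", "blomberg_k", "k_mult", "retained_components"]


@dataclass(frozen=True)
class SignalResult:
    """A permutation-tested phylogenetic signal statistic."""

    statistic: float
    p: float
    effect_size: float
    n_perm: int
    seed: int | None
    n_components: int | None = None


def retained_components(explained_variance_ratio: np.ndarray, threshold: float) -> int:
    """Smallest leading set of components with cumulative variance >= threshold."""
    cum = np.cumsum(explained_variance_ratio)
    return int(np.searchsorted(cum, threshold - 1e-12) + 1)


def _prepare(tree: dendropy.Tree, labels):
    order, C = phylo_vcv(tree, order=list(labels))
    n = C.shape[0]
    L = linalg.cholesky(C, lower=True)
    Cinv_one = linalg.cho_solve((L, True), np.ones(n))
    w = Cinv_one / Cinv_one.sum()  # GLS weights for the root state
    # sum of all elements of C^-1 equals 1' C^-1 1
    expected = (np.trace(C) - n / Cinv_one.sum()) / (n - 1)
    return C, L, w, float(expected)


def _k_batch(Y: np.ndarray, perms: np.ndarray, L: np.ndarray, w: np.ndarray,
             expected: float) -> np.ndarray:
    """K (or K_mult) for each row-permuted copy of the trait matrix Y."""
    B = perms.shape[0]
    n, p = Y.shape
    Yp = Y[perms]                                     # (B, n, p)
    a = np.einsum("n,bnp->bp", w, Yp)                 # GLS mean per column
    R = Yp - a[:, None, :]
    num = np.einsum("bnp,bnp->b", R, R)
    flat = np.ascontiguousarray(R.transpose(1, 0, 2).reshape(n, B * p))
    S = linalg.solve_triangular(L, flat, lower=True)
    den = (S * S).reshape(n, B, p).sum(axis=(0, 2))
    return (num / den) / expected


def _signal(tree, Y: np.ndarray, labels, n_perm: int, seed, n_components=None,
            log_effect: bool = False, chunk: int = 2000) -> SignalResult:
    n = Y.shape[0]
    if np.allclose(Y.std(axis=0), 0):
        raise ValueError("constant trait: phylogenetic signal undefined")
    C, L, w, expected = _prepare(tree, labels)
    obs = float(_k_batch(Y, np.arange(n)[None, :], L, w, expected)[0])
    rng = np.random.default_rng(seed)
    perm_stats = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        perms = np.array([rng.permutation(n) for _ in range(b)])
        perm_stats[done:done + b] = _k_batch(Y, perms, L, w, expected)
        done += b
    p = (np.count_nonzero(perm_stats >= obs) + 1) / (n_perm + 1)
    if n_perm < 2:
        z = float("nan")
    elif log_effect:
        z = (np.log(obs) - np.log(perm_stats).mean()) / np.log(perm_stats).std(ddof=1)
    else:
        z = (obs - perm_stats.mean()) / perm_stats.std(ddof=1)
    return SignalResult(obs, float(p), float(z), n_perm, seed, n_components)


def blomberg_k(
    tree: dendropy.Tree,
    trait: pd.Series | Mapping[str, float],
    n_perm: int = 50_000,
    seed: int | None = None,
    log_effect: bool = False,
) -> SignalResult:
    """Blomberg's K of a tip trait with tip-shuffling permutation test."""
    trait = pd.Series(dict(trait), dtype=float)
    return _signal(tree, trait.to_numpy()[:, None], trait.index, n_perm, seed,
                   log_effect=log_effect)


def k_mult(
    tree: dendropy.Tree,
    traits: pd.DataFrame,
    n_perm: int = 50_000,
    seed: int | None = None,
    variance_retained: float | None = 0.95,
    log_effect: bool = False,
) -> SignalResult:
    """Multivariate phylogenetic signal of a species x variables matrix.

    Rows are species means (tip labels on the index). When
    ``variance_retained`` is given the matrix is first reduced to the
    smallest set of leading principal components reaching that
    cumulative explained variance (PCA centered, not scaled).
    """
    Y = traits.to_numpy(dtype=float)
    n = Y.shape[0]
    n_components = None
    if variance_retained is not None and Y.shape[1] > 1:
        from sklearn.decomposition import PCA

        pca = PCA()
        scores = pca.fit_transform(Y)
        m = retained_components(pca.explained_variance_ratio_, variance_retained)
        if m > n - 1:
            raise ValueError(
                f"retaining {m} components for {n} species; need at most n - 1"
            )
        Y = scores[:, :m]
        n_components = m
    return _signal(tree, Y, traits.index, n_perm, seed, n_components, log_effect)
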