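"""Trait-evolution models on trees with fossil tips: BM, EB, OU, BMM, OUM.

All five models are Gaussian: the tip values are one draw from a
multivariate normal whose mean and covariance are functions of the tree
and the model parameters.

* BM  -- Brownian motion: cov = sigma^2 * C (C = shared path lengths),
  mean = root state z0. 2 parameters.
* EB  -- early burst: BM whose rate decays as sigma^2 * exp(r t) with
  r <= 0; accumulated covariance (exp(r C) - 1) / r. 3 parameters.
* OU  -- single-optimum Ornstein-Uhlenbeck. 3 parameters.
* BMM -- Brownian motion with one rate per regime: cov is the sum of
  regime-specific path-length matrices weighted by their sigma^2.
  3 parameters for two regimes.
* OUM -- OU with one optimum per regime (common alpha and sigma^2): the
  tip expectation is an exponentially weighted average of the optima
  crossed along the root-to-tip path. 4 parameters for two regimes.

The OU family supports three root treatments:

* ``"theta"`` (default) -- the root state equals the root regime's
  optimum; cov(i, j) = sigma^2/(2 alpha) * (exp(-alpha d_ij) -
  exp(-alpha (T_i + T_j))) with d_ij the patristic distance and T the
  tip depths. This nests BM exactly as alpha -> 0 and adds no
  parameter.
* ``"stationary"`` -- the root is drawn from the stationary
  distribution around the root optimum; cov(i, j) = sigma^2/(2 alpha) *
  exp(-alpha d_ij). No extra parameter.
* ``"free"`` -- a freely estimated deterministic root state (one extra
  parameter; OUM then has 5).

All forms are exact on non-ultrametric (fossil-bearing) trees.

Fitting profiles the mean parameters and the scale out of the Gaussian
likelihood, leaving at most a one-dimensional search (EB rate, OU/OUM
alpha on the log scale, BMM rate ratio) solved by bounded quasi-Newton
steps from several seeded restarts. Models are compared by
AIC = 2k - 2 lnL, and the phylogenetic half-life of an OU process is
ln(2)/alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import dendropy
from scipy import linalg, optimize

from .phylo import node_depths, patristic_matrix, phylo_vcv, tree_height, _find_mrca

__all__ = [
    "MODELS",
    "EvoFit",
    "rescale_tree_height",
    "paint_regimes",
    "regime_segments",
    "fit_trait_model",
    "trait_loglik",
    "compare_models",
    "half_life",
    "model_moments",
    "tree_structure",
]

MODELS = ("BM", "EB", "OU", "BMM", "OUM")

BACKGROUND, SHIFTED = 1, 2  # regime labels: 1 outside the painted clade, 2 inside
ROOT_MODES = ("theta", "stationary", "free")


@dataclass
class EvoFit:
    """A fitted trait-evolution model."""

    model: str
    params: dict
    lnl: float
    k: int
    converged: bool
    root: str = "theta"
    regime_label: str | None = None

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.lnl

    @property
    def half_life(self) -> float | None:
        alpha = self.params.get("alpha")
        return None if alpha is None else half_life(alpha)


def half_life(alpha: float) -> float:
    """Time for an OU process to cover half the distance to its optimum."""
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    return float(np.log(2.0) / alpha)


def rescale_tree_height(tree: dendropy.Tree, target: float = 1.0) -> dendropy.Tree:
    """Multiply all branch lengths so the maximal root-to-tip depth is ``target``."""
    height = tree_height(tree)
    if height <= 0:
        raise ValueError("tree has zero height")
    tree = tree.clone(depth=1)
    factor = target / height
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length * factor
    return tree


def paint_regimes(tree: dendropy.Tree, clade: str | Sequence[str]) -> dict:
    """Two-regime painting: the named clade (from its stem edge) vs the rest.

    ``clade`` is a tip label or a collection of tip labels whose MRCA
    roots the shifted regime. Returns a node -> regime map keyed by the
    node whose subtending edge carries the regime (the root is excluded;
    its state belongs to the background regime).
    """
    try:
        shift_node = _find_mrca(tree, clade)
    except ValueError as exc:
        tips = sorted(l.taxon.label for l in tree.leaf_node_iter())
        raise ValueError(f"{exc}; available tips: {tips}") from exc
    regimes: dict = {}
    inside = set(shift_node.preorder_iter())
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        regimes[nd] = SHIFTED if nd in inside else BACKGROUND
    return regimes


def regime_segments(tree: dendropy.Tree, regimes: Mapping, order: Sequence[str]):
    """Per-tip root-to-tip segments: list of (start_depth, end_depth, regime)."""
    depths = node_depths(tree)
    segs = {}
    for leaf in tree.leaf_node_iter():
        path = []
        nd = leaf
        while nd.parent_node is not None:
            path.append((depths[nd.parent_node], depths[nd], regimes[nd]))
            nd = nd.parent_node
        segs[leaf.taxon.label] = path[::-1]
    return [segs[lab] for lab in order]


def tree_structure(tree: dendropy.Tree, order: Sequence[str], regimes=None) -> dict:
    """Precomputed tree matrices shared by simulation and fitting."""
    if regimes is None:
        order, C = phylo_vcv(tree, order=order)
        Cr = None
    else:
        order, C, Cr = phylo_vcv(tree, order=order, regimes=regimes)
        for r in (BACKGROUND, SHIFTED):  # a root-wide painting leaves one empty
            Cr.setdefault(r, np.zeros_like(C))
    st = {
        "order": order,
        "C": C,
        "Cr": Cr,
        "D": patristic_matrix(C),
        "T": np.diag(C).copy(),
        "height": float(np.diag(C).max()),
    }
    if regimes is not None:
        st["segments"] = regime_segments(tree, regimes, order)
    return st


# ---------------------------------------------------------------------------
# moments

def _ou_corr(alpha: float, st: dict, root: str) -> np.ndarray:
    """OU correlation structure (the sigma^2/(2 alpha) scale left out)."""
    V = np.exp(-alpha * st["D"])
    if root in ("theta", "free"):
        T = st["T"]
        V = V - np.exp(-alpha * (T[:, None] + T[None, :]))
    return V


def _ou_weights(alpha: float, st: dict, root: str) -> np.ndarray:
    """Regime weights of the optima in each tip's expectation (OUM design).

    Segment (a, b) of regime r on the path to a tip of depth T
    contributes exp(-alpha (T - b)) - exp(-alpha (T - a)) to column r.
    The residual exp(-alpha T) weight belongs to the root state: folded
    into the background column under 'theta'/'stationary' roots, or
    into an extra trailing column under a 'free' root.
    """
    segments, T = st["segments"], st["T"]
    n = len(segments)
    W = np.zeros((n, 3 if root == "free" else 2))
    for i, path in enumerate(segments):
        for a, b, regime in path:
            W[i, regime - 1] += np.exp(-alpha * (T[i] - b)) - np.exp(-alpha * (T[i] - a))
        if root == "free":
            W[i, -1] = np.exp(-alpha * T[i])
        else:
            W[i, BACKGROUND - 1] += np.exp(-alpha * T[i])
    return W


def model_moments(model: str, params: dict, st: dict, root: str = "theta"):
    """Mean vector and full covariance matrix of the tip distribution."""
    C, T = st["C"], st["T"]
    n = C.shape[0]
    if model == "BM":
        return np.full(n, params["z0"]), params["sigma2"] * C
    if model == "EB":
        r = params["r"]
        G = C.copy() if r == 0 else np.expm1(r * C) / r
        return np.full(n, params["z0"]), params["sigma2"] * G
    if model == "BMM":
        Cr = st["Cr"]
        V = params["sigma2_1"] * Cr[BACKGROUND] + params["sigma2_2"] * Cr[SHIFTED]
        return np.full(n, params["z0"]), V
    if model in ("OU", "OUM"):
        alpha = params["alpha"]
        v = params["sigma2"] / (2.0 * alpha)
        V = v * _ou_corr(alpha, st, root)
        if model == "OU":
            if root == "free":
                mean = params["theta"] + (params["z0"] - params["theta"]) * np.exp(-alpha * T)
            else:
                mean = np.full(n, params["theta"])
        else:
            W = _ou_weights(alpha, st, root)
            coef = [params["theta_1"], params["theta_2"]]
            if root == "free":
                coef.append(params["z0"])
            mean = W @ np.asarray(coef)
        return mean, V
    raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")


# ---------------------------------------------------------------------------
# likelihood

def _gls_profile(V: np.ndarray, X: np.ndarray, y: np.ndarray):
    """ML profile of y ~ N(X beta, s2 V): returns (lnl, beta, s2)."""
    n = y.size
    try:
        L = linalg.cholesky(V, lower=True)
    except linalg.LinAlgError:
        return -np.inf, np.full(X.shape[1], np.nan), np.nan
    Xt = linalg.solve_triangular(L, X, lower=True)
    yt = linalg.solve_triangular(L, y, lower=True)
    beta, *_ = np.linalg.lstsq(Xt, yt, rcond=None)
    r = yt - Xt @ beta
    s2 = float(r @ r) / n
    if s2 <= 0 or not np.isfinite(s2):
        return -np.inf, beta, s2
    lnl = -0.5 * n * (np.log(2.0 * np.pi) + np.log(s2) + 1.0) - np.sum(np.log(np.diag(L)))
    return float(lnl), beta, s2


def trait_loglik(
    tree: dendropy.Tree,
    trait: pd.Series | Mapping[str, float],
    model: str,
    params: dict,
    regimes: Mapping | None = None,
    root: str = "theta",
) -> float:
    """Exact Gaussian log-likelihood of a trait under explicit parameters."""
    trait = pd.Series(dict(trait), dtype=float)
    st = tree_structure(tree, list(trait.index), regimes=regimes)
    mean, V = model_moments(model, params, st, root=root)
    y = trait.to_numpy() - mean
    L = linalg.cholesky(V, lower=True)
    z = linalg.solve_triangular(L, y, lower=True)
    n = y.size
    return float(-0.5 * (n * np.log(2.0 * np.pi) + z @ z) - np.sum(np.log(np.diag(L))))


def _optimize_scalar(objective, bounds, rng, n_restarts):
    """Minimize a 1-d objective with bounded L-BFGS-B from seeded restarts."""
    lo, hi = bounds
    starts = list(np.linspace(lo, hi, 5)) + list(rng.uniform(lo, hi, size=n_restarts))
    best, best_x, ok = np.inf, None, False
    for x0 in starts:
        res = optimize.minimize(objective, x0=[x0], method="L-BFGS-B", bounds=[(lo, hi)])
        if res.fun < best:
            best, best_x, ok = float(res.fun), float(res.x[0]), bool(res.success)
    return best_x, -best, ok


def fit_trait_model(
    tree: dendropy.Tree,
    trait: pd.Series | Mapping[str, float],
    model: str,
    regimes: Mapping | None = None,
    root: str = "theta",
    n_restarts: int = 10,
    seed: int | None = 0,
) -> EvoFit:
    """Maximum-likelihood fit of one trait-evolution model.

    ``trait`` maps tip labels to values and must cover every tip used.
    ``regimes`` (a node -> regime map from :func:`paint_regimes`) is
    required for BMM/OUM; ``root`` picks the OU-family root treatment.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    if root not in ROOT_MODES:
        raise ValueError(f"unknown root mode {root!r}; expected one of {ROOT_MODES}")
    if model in ("BMM", "OUM") and regimes is None:
        raise ValueError(f"{model} requires a regime painting")
    trait = pd.Series(dict(trait), dtype=float)
    order = list(trait.index)
    st = tree_structure(tree, order, regimes=regimes if model in ("BMM", "OUM") else None)
    y = trait.to_numpy()
    n = y.size
    ones = np.ones((n, 1))
    rng = np.random.default_rng(seed)
    height = st["height"]

    if model == "BM":
        lnl, beta, s2 = _gls_profile(st["C"], ones, y)
        return EvoFit("BM", {"sigma2": s2, "z0": float(beta[0])}, lnl, 2, True, root)

    if model == "EB":
        def neg(x):
            r = x[0]
            G = st["C"] if r == 0 else np.expm1(r * st["C"]) / r
            return -_gls_profile(G, ones, y)[0]

        r_hat, lnl, ok = _optimize_scalar(neg, (-10.0 / height, 0.0), rng, n_restarts)
        G = st["C"] if r_hat == 0 else np.expm1(r_hat * st["C"]) / r_hat
        _, beta, s2 = _gls_profile(G, ones, y)
        return EvoFit("EB", {"sigma2": s2, "r": r_hat, "z0": float(beta[0])}, lnl, 3, ok, root)

    if model == "BMM":
        Cr = st["Cr"]

        def neg(x):
            w = np.exp(x[0])
            return -_gls_profile(Cr[BACKGROUND] + w * Cr[SHIFTED], ones, y)[0]

        x_hat, lnl, ok = _optimize_scalar(neg, (-12.0, 12.0), rng, n_restarts)
        w = np.exp(x_hat)
        _, beta, s2 = _gls_profile(Cr[BACKGROUND] + w * Cr[SHIFTED], ones, y)
        params = {"sigma2_1": s2, "sigma2_2": w * s2, "z0": float(beta[0])}
        return EvoFit("BMM", params, lnl, 3, ok, root)

    # OU family: 1-d search over log(alpha); mean design depends on alpha
    log_bounds = (np.log(1e-4 / height), np.log(1e3 / height))
    T = st["T"]

    def design(alpha):
        if model == "OU":
            if root == "free":
                e = np.exp(-alpha * T)
                return np.column_stack([1.0 - e, e])
            return ones
        return _ou_weights(alpha, st, root)

    def neg(x):
        alpha = np.exp(x[0])
        return -_gls_profile(_ou_corr(alpha, st, root), design(alpha), y)[0]

    x_hat, lnl, ok = _optimize_scalar(neg, log_bounds, rng, n_restarts)
    alpha = float(np.exp(x_hat))
    _, beta, v = _gls_profile(_ou_corr(alpha, st, root), design(alpha), y)
    sigma2 = 2.0 * alpha * v
    if model == "OU":
        params = {"sigma2": sigma2, "alpha": alpha, "theta": float(beta[0])}
        if root == "free":
            params["z0"] = float(beta[1])
        return EvoFit("OU", params, lnl, 4 if root == "free" else 3, ok, root)
    params = {
        "sigma2": sigma2, "alpha": alpha,
        "theta_1": float(beta[0]), "theta_2": float(beta[1]),
    }
    if root == "free":
        params["z0"] = float(beta[2])
    return EvoFit("OUM", params, lnl, 5 if root == "free" else 4, ok, root)


def compare_models(fits: Sequence[EvoFit]) -> pd.DataFrame:
    """AIC ranking of fits of the same trait on the same tree."""
    if not fits:
        raise ValueError("no fits to compare")
    rows = []
    for f in fits:
        rows.append(
            {
                "model": f.model + (f" ({f.regime_label})" if f.regime_label else ""),
                "lnL": f.lnl,
                "k": f.k,
                "aic": f.aic,
                "half_life": f.half_life,
                "converged": f.converged,
            }
        )
    table = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].iloc[0]
    return table
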