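"""Trait-evolution models: likelihood oracle, nested limits, recovery, AIC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from vertdescent import synth
from vertdescent.evomodel import (
    EvoFit,
    compare_models,
    fit_trait_model,
    half_life,
    model_moments,
    paint_regimes,
    rescale_tree_height,
    trait_loglik,
    tree_structure,
)
from vertdescent.phylo import node_depths, read_newick, tree_height


# ---------------------------------------------------------------------------
# independent covariance oracle: brute-force path enumeration

def _paths(tree):
    """Per tip label: list of (parent_depth, node_depth, node) segments."""
    depths = node_depths(tree)
    out = {}
    for leaf in tree.leaf_node_iter():
        segs, nd = [], leaf
        while nd.parent_node is not None:
            segs.append((depths[nd.parent_node], depths[nd], nd))
            nd = nd.parent_node
        out[leaf.taxon.label] = segs[::-1]
    return out


def _shared_time(pa, pb):
    """Shared root-to-MRCA time of two tips from their segment lists."""
    t = 0.0
    for (a0, a1, na), (b0, b1, nb) in zip(pa, pb):
        if na is not nb:
            break
        t = a1
    return t


def _oracle_moments(tree, model, params, regime_tips=None, root="theta"):
    """Mean and covariance built by independent path enumeration."""
    paths = _paths(tree)
    labels = sorted(paths)
    n = len(labels)
    depths = {lab: paths[lab][-1][1] if paths[lab] else 0.0 for lab in labels}
    shared = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            shared[i, j] = depths[a] if i == j else _shared_time(paths[a], paths[b])
    if model == "BM":
        return labels, np.full(n, params["z0"]), params["sigma2"] * shared
    if model == "EB":
        r = params["r"]
        G = shared if r == 0 else (np.exp(r * shared) - 1.0) / r
        return labels, np.full(n, params["z0"]), params["sigma2"] * G
    if model == "BMM":
        inside = set(regime_tips)
        V = np.zeros((n, n))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                segs_a = paths[a]
                segs_b = paths[b]
                for (a0, a1, na), (b0, b1, nb) in zip(segs_a, segs_b):
                    if na is not nb and i != j:
                        break
                    tips_below = {l.taxon.label for l in na.leaf_iter()}
                    rate = params["sigma2_2"] if tips_below <= inside else params["sigma2_1"]
                    V[i, j] += rate * (a1 - a0)
        return labels, np.full(n, params["z0"]), V
    # OU family
    alpha, v = params["alpha"], params["sigma2"] / (2 * params["alpha"])
    V = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            ta = _shared_time(paths[a], paths[b]) if i != j else depths[a]
            d = depths[a] + depths[b] - 2 * ta
            V[i, j] = v * np.exp(-alpha * d)
            if root in ("theta", "free"):
                V[i, j] -= v * np.exp(-alpha * (depths[a] + depths[b]))
    if model == "OU":
        mean = np.full(n, params["theta"])
    else:
        inside = set(regime_tips)
        mean = np.zeros(n)
        for i, a in enumerate(labels):
            T = depths[a]
            w2 = 0.0
            for a0, a1, nd in paths[a]:
                tips_below = {l.taxon.label for l in nd.leaf_iter()}
                if tips_below <= inside:
                    w2 += np.exp(-alpha * (T - a1)) - np.exp(-alpha * (T - a0))
            mean[i] = params["theta_2"] * w2 + params["theta_1"] * (1.0 - w2)
    return labels, mean, V


SMALL_TREES = [
    "((A:1,B:1):1,C:2);",
    "(((A:0.5,B:0.7):0.6,C:1.3):0.9,(D:1.1,E:0.4):1.2);",
    "((A:1,(B:0.5,C:0.8):0.7):1,(D:2.2,(E:0.9,F:1.3):0.6):0.4);",
]


@pytest.mark.parametrize("newick", SMALL_TREES)
@pytest.mark.parametrize("model", ["BM", "EB", "OU", "BMM", "OUM"])
def test_loglik_matches_direct_mvn_oracle(newick, model):
    """Each model's lnL on small trees equals a scipy MVN density built
    from an independently enumerated covariance (1e-8 agreement)."""
    tree = read_newick(newick)
    labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
    from vertdescent.phylo import _find_mrca

    mrca = _find_mrca(tree, labels[:2])
    regime_tips = sorted(l.taxon.label for l in mrca.leaf_iter())
    params = {
        "BM": {"sigma2": 0.8, "z0": 1.5},
        "EB": {"sigma2": 0.8, "r": -0.9, "z0": 1.5},
        "OU": {"sigma2": 1.2, "alpha": 1.7, "theta": 2.0},
        "BMM": {"sigma2_1": 0.5, "sigma2_2": 2.5, "z0": 1.0},
        "OUM": {"sigma2": 1.2, "alpha": 1.7, "theta_1": 0.5, "theta_2": 3.0},
    }[model]
    rng = np.random.default_rng(0)
    y = pd.Series(rng.normal(1.0, 1.0, size=len(labels)), index=labels)
    regimes = paint_regimes(tree, regime_tips) if model in ("BMM", "OUM") else None
    lnl = trait_loglik(tree, y, model, params, regimes=regimes)
    olabels, mean, V = _oracle_moments(tree, model, params, regime_tips)
    yv = y[olabels].to_numpy()
    expected = sps.multivariate_normal.logpdf(yv, mean=mean, cov=V)
    assert lnl == pytest.approx(expected, abs=1e-8)


# ---------------------------------------------------------------------------
# limits and nesting

def test_eb_with_zero_rate_equals_bm(extant_tree):
    y = synth.sim_traits_on_tree(extant_tree, "BM", {"sigma2": 2.0, "z0": 5.0},
                                 seed=1).iloc[0]
    bm = fit_trait_model(extant_tree, y, "BM")
    lnl_eb0 = trait_loglik(extant_tree, y, "EB",
                           {"sigma2": bm.params["sigma2"], "r": 0.0,
                            "z0": bm.params["z0"]})
    assert lnl_eb0 == pytest.approx(bm.lnl, abs=1e-10)


def test_ou_alpha_to_zero_reproduces_bm_loglik(extant_tree):
    y = synth.sim_traits_on_tree(extant_tree, "BM", {"sigma2": 2.0, "z0": 5.0},
                                 seed=2).iloc[0]
    bm = fit_trait_model(extant_tree, y, "BM")
    lnl_ou = trait_loglik(extant_tree, y, "OU",
                          {"alpha": 1e-9, "sigma2": bm.params["sigma2"],
                           "theta": bm.params["z0"]})
    assert lnl_ou == pytest.approx(bm.lnl, abs=1e-4)


def test_nesting_on_same_data(study_tree):
    """More general models never fit worse than their special cases."""
    unit = rescale_tree_height(study_tree, 1.0)
    labels = sorted(l.taxon.label for l in unit.leaf_node_iter())
    regimes = paint_regimes(unit, labels[:6])
    eps = 1e-3
    for seed in range(3):
        y = synth.sim_traits_on_tree(unit, "OU",
                                     {"sigma2": 4.0, "alpha": 2.0, "theta": 1.0},
                                     seed=seed).iloc[0]
        bm = fit_trait_model(unit, y, "BM")
        eb = fit_trait_model(unit, y, "EB", n_restarts=3)
        ou = fit_trait_model(unit, y, "OU", n_restarts=3)
        oum = fit_trait_model(unit, y, "OUM", regimes=regimes, n_restarts=3)
        bmm = fit_trait_model(unit, y, "BMM", regimes=regimes, n_restarts=3)
        assert eb.lnl >= bm.lnl - eps
        assert ou.lnl >= bm.lnl - eps
        assert oum.lnl >= ou.lnl - eps
        assert bmm.lnl >= bm.lnl - eps


def test_rescaling_reparameterizes_alpha(extant_tree):
    """Halving the tree height doubles alpha and leaves max lnL equal."""
    unit = rescale_tree_height(extant_tree, 1.0)
    half = rescale_tree_height(extant_tree, 0.5)
    y = synth.sim_traits_on_tree(unit, "OU",
                                 {"sigma2": 6.0, "alpha": 3.0, "theta": 0.0},
                                 seed=3).iloc[0]
    f1 = fit_trait_model(unit, y, "OU", n_restarts=4)
    f2 = fit_trait_model(half, y, "OU", n_restarts=4)
    assert f2.params["alpha"] == pytest.approx(2 * f1.params["alpha"], rel=1e-3)
    assert f2.lnl == pytest.approx(f1.lnl, abs=1e-5)


# ---------------------------------------------------------------------------
# rescaling and regimes

def test_rescale_tree_height():
    t = read_newick("((A:1,B:1):1,C:2);")
    r = rescale_tree_height(t, 1.0)
    assert tree_height(r) == pytest.approx(1.0)
    assert tree_height(rescale_tree_height(r, 1.0)) == pytest.approx(1.0)


def test_paint_regimes_cherry_counts():
    t = read_newick("(((A:1,B:1):1,C:2):1,D:3);")
    regimes = paint_regimes(t, ("A", "B"))
    shifted = [nd for nd, r in regimes.items() if r == 2]
    assert len(shifted) == 3  # stem + 2 terminal edges
    rootwide = paint_regimes(t, ("A", "B", "C", "D"))
    assert all(r == 2 for r in rootwide.values())


def _proper_clade(tree, lo=4, hi=14):
    """Tip labels of some internal, non-root clade of intermediate size."""
    for nd in tree.preorder_node_iter():
        tips = [l.taxon.label for l in nd.leaf_iter()]
        if nd.parent_node is not None and lo <= len(tips) <= hi:
            return tips
    raise AssertionError("no suitable clade in fixture tree")


def test_paint_regimes_matches_traversal_oracle(study_tree):
    clade = _proper_clade(study_tree)
    regimes = paint_regimes(study_tree, clade)
    from vertdescent.phylo import _find_mrca

    mrca = _find_mrca(study_tree, clade)
    expected_shifted = sum(1 for _ in mrca.preorder_iter())
    assert sum(1 for r in regimes.values() if r == 2) == expected_shifted
    assert len(regimes) == sum(1 for nd in study_tree.preorder_node_iter()
                               if nd.parent_node is not None)


def test_paint_regimes_unknown_clade_lists_tips():
    t = read_newick("((A:1,B:1):1,C:2);")
    with pytest.raises(ValueError, match="available tips"):
        paint_regimes(t, ("A", "Z"))


# ---------------------------------------------------------------------------
# model comparison and half-life

def test_aic_formula_and_ranking():
    f1 = EvoFit("BM", {}, lnl=-10.0, k=3, converged=True)
    assert f1.aic == pytest.approx(26.0)
    f2 = EvoFit("OU", {}, lnl=-10.0, k=2, converged=True)
    table = compare_models([f1, f2])
    assert table.iloc[0]["model"] == "OU"  # same lnL, fewer params wins
    assert table["delta_aic"].iloc[0] == 0.0
    assert (table["delta_aic"] >= 0).all()


def test_bm_data_prefers_bm_by_aic(extant_tree):
    unit = rescale_tree_height(extant_tree, 1.0)
    wins = 0
    for seed in range(20):
        y = synth.sim_traits_on_tree(unit, "BM", {"sigma2": 1.0, "z0": 0.0},
                                     seed=50 + seed).iloc[0]
        bm = fit_trait_model(unit, y, "BM")
        ou = fit_trait_model(unit, y, "OU", n_restarts=3)
        eb = fit_trait_model(unit, y, "EB", n_restarts=3)
        best = min([bm, ou, eb], key=lambda f: f.aic)
        wins += bm.aic <= best.aic + 2.0
    assert wins >= 16  # BM within 2 AIC of the best in >= 80%


@pytest.mark.parametrize(
    "alpha, expected",
    [(np.log(2.0), 1.0), (7.49, 0.093), (7.51, 0.092)],
)
def test_half_life(alpha, expected):
    assert half_life(alpha) == pytest.approx(expected, abs=5e-4)


def test_half_life_requires_positive_alpha():
    with pytest.raises(ValueError):
        half_life(0.0)


def test_oum_recovery_smoke(study_tree):
    """Thetas recovered near truth on the fossil-bearing study-scale tree."""
    unit = rescale_tree_height(study_tree, 1.0)
    regimes = paint_regimes(unit, _proper_clade(unit, 8, 14))
    true = {"alpha": 7.5, "sigma2": 1500.0, "theta_1": 95.0, "theta_2": 45.0}
    th1, th2 = [], []
    for seed in range(10):
        y = synth.sim_traits_on_tree(unit, "OUM", true, seed=seed, regimes=regimes).iloc[0]
        f = fit_trait_model(unit, y, "OUM", regimes=regimes, n_restarts=3, seed=seed)
        th1.append(f.params["theta_1"])
        th2.append(f.params["theta_2"])
    assert abs(np.median(th1) - 95.0) < 10.0
    assert abs(np.median(th2) - 45.0) < 10.0
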