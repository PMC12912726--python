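"""Strategy tables, bootstrap/rank statistics, BH correction, correlates."""

import numpy as np
import pandas as pd
import pytest

from vertdescent import synth
from vertdescent.ethogram import (
    adjust_family,
    bh_adjust,
    bootstrap_support_effect_test,
    gait_fraction_contrast,
    gait_pca_group_test,
    kinematic_contrast,
    spearman_morph_correlates,
    tabulate_strategy_proportions,
)


def _bouts(rows):
    return pd.DataFrame(rows)


def descent(species, individual, support, strategy, n=1):
    return [dict(species=species, individual=individual, support=support,
                 direction="descent", strategy=strategy)] * n


# ---------------------------------------------------------------------------
# strategy proportions

def test_single_individual_all_head_first():
    table = tabulate_strategy_proportions(_bouts(descent("sp", "i1", "small", "head_first", 10)))
    row = table.loc[("sp", "small")]
    assert row["head_first"] == pytest.approx(100.0)
    assert row["n_individuals"] == 1 and row["n_events"] == 10


def test_two_stage_averaging_over_individuals():
    rows = descent("sp", "i1", "small", "head_first", 10)
    rows += descent("sp", "i2", "small", "tail_first", 2)
    table = tabulate_strategy_proportions(_bouts(rows))
    row = table.loc[("sp", "small")]
    # individuals count equally despite 10 vs 2 events
    assert row["head_first"] == pytest.approx(50.0)
    assert row["tail_first"] == pytest.approx(50.0)
    assert row["side"] == pytest.approx(0.0)


def test_unbalanced_counts_match_hand_average():
    rows = descent("sp", "i1", "small", "head_first", 3) + descent("sp", "i1", "small", "side", 1)
    rows += descent("sp", "i2", "small", "head_first", 1) + descent("sp", "i2", "small", "side", 4)
    table = tabulate_strategy_proportions(_bouts(rows))
    # i1: 75/25; i2: 20/80 -> mean 47.5 / 52.5
    assert table.loc[("sp", "small"), "head_first"] == pytest.approx(47.5)
    assert table.loc[("sp", "small"), "side"] == pytest.approx(52.5)


def test_proportions_sum_to_100():
    bouts = synth.gen_study_table(synth.SynthConfig(seed=1))
    table = tabulate_strategy_proportions(bouts)
    sums = table[["head_first", "side", "tail_first"]].sum(axis=1)
    np.testing.assert_allclose(sums, 100.0, atol=1e-9)


# ---------------------------------------------------------------------------
# BH adjustment

def test_bh_worked_example():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)


def test_bh_identities():
    assert bh_adjust([0.37])[0] == pytest.approx(0.37)
    np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2] * 3)


def test_bh_order_invariance_and_monotonicity():
    rng = np.random.default_rng(0)
    p = rng.uniform(size=12)
    adj = bh_adjust(p)
    perm = rng.permutation(12)
    np.testing.assert_allclose(bh_adjust(p[perm]), adj[perm], atol=1e-12)
    # a flat adjusted set is a fixed point of the step-up procedure
    flat = bh_adjust([0.01, 0.02, 0.03, 0.04])
    np.testing.assert_allclose(bh_adjust(flat), flat, atol=1e-12)
    assert (adj >= p - 1e-15).all()


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])


# ---------------------------------------------------------------------------
# support-effect bootstrap test

def test_support_effect_requires_two_supports():
    rows = descent("sp", "i1", "small", "head_first", 5)
    with pytest.raises(ValueError):
        bootstrap_support_effect_test(_bouts(rows), "sp", seed=0)


def test_support_effect_maximal_separation():
    rows = []
    for i in range(4):
        rows += descent("sp", f"i{i}", "small", "head_first", 10)
        rows += descent("sp", f"i{i}", "large", "tail_first", 10)
    res = bootstrap_support_effect_test(_bouts(rows), "sp", seed=1)
    assert res.p_raw < 0.001


def test_support_effect_dispatch_rule():
    rng = np.random.default_rng(2)
    rows = []
    for i in range(6):
        for s in ("small", "large"):
            for strat in rng.choice(["head_first", "side", "tail_first"], size=12):
                rows += descent("sp3", f"i{i}", s, strat)
            for strat in rng.choice(["head_first", "side"], size=12):
                rows += descent("sp2", f"i{i}", s, strat)
    three = bootstrap_support_effect_test(_bouts([r for r in rows if r["species"] == "sp3"]),
                                          "sp3", seed=3)
    two = bootstrap_support_effect_test(_bouts([r for r in rows if r["species"] == "sp2"]),
                                        "sp2", seed=3)
    assert three.method == "manova-wilks"
    assert two.method == "anova"


def test_support_effect_reproducible():
    bouts = synth.gen_study_table(synth.SynthConfig(seed=5))
    sp = bouts["species"].iloc[0]
    a = bootstrap_support_effect_test(bouts, sp, seed=11)
    b = bootstrap_support_effect_test(bouts, sp, seed=11)
    assert (a.statistic, a.p_raw) == (b.statistic, b.p_raw)


# ---------------------------------------------------------------------------
# kinematic contrasts

def test_contrast_identical_samples_null():
    x = np.full(30, 1.7)
    res = kinematic_contrast(x, x, seed=0)
    assert res.extra["percent_change"] == pytest.approx(0.0)
    assert res.p_raw == pytest.approx(1.0)


def test_contrast_30_percent_reduction():
    rng = np.random.default_rng(1)
    asc = rng.lognormal(0, 0.2, size=400)
    res = kinematic_contrast(asc, asc * 0.7, n_each=200, seed=2)
    assert res.extra["percent_change"] == pytest.approx(-30.0, abs=3.0)
    assert res.p_raw < 0.01


def test_contrast_power_increases_with_shift():
    rng = np.random.default_rng(3)
    power = []
    for shift in (0.0, 0.3, 0.8):
        rej = 0
        for rep in range(60):
            a = rng.normal(0, 1, 200)
            d = rng.normal(shift, 1, 200)
            rej += kinematic_contrast(a, d, seed=rep).p_raw < 0.05
        power.append(rej / 60)
    assert power[0] < power[1] < power[2]


def test_contrast_requires_events():
    with pytest.raises(ValueError):
        kinematic_contrast([], [1.0], seed=0)


# ---------------------------------------------------------------------------
# gait-fraction contrast

def _gait_bouts(n_species, p_asc, p_desc, n=40, seed=0):
    r = np.random.default_rng(seed)
    frames = []
    for s in range(n_species):
        for d, p in (("ascent", p_asc), ("descent", p_desc)):
            frames.append(pd.DataFrame(dict(
                species=f"s{s}", support="medium", direction=d,
                symmetry=r.random(n) < p)))
    return pd.concat(frames, ignore_index=True)


def test_gait_fraction_identical_mixes_ns():
    rejections = sum(
        gait_fraction_contrast(_gait_bouts(8, 0.5, 0.5, n=200, seed=4 + i),
                               "medium", seed=50 + i).p_raw < 0.05
        for i in range(10)
    )
    assert rejections <= 3


def test_gait_fraction_maximal_separation():
    res = gait_fraction_contrast(_gait_bouts(8, 1.0, 0.0, seed=6), "medium", seed=7)
    assert res.p_raw < 0.001
    assert res.extra["mean_fraction_change"] == pytest.approx(-1.0)


def test_gait_fraction_all_tied_p_one():
    res = gait_fraction_contrast(_gait_bouts(5, 1.0, 1.0, seed=8), "medium", seed=9)
    assert res.p_raw == 1.0


# ---------------------------------------------------------------------------
# PCA + MANOVA group test

def test_gait_pca_disjoint_repertoires():
    rng = np.random.default_rng(10)
    n = 30
    a = np.abs(rng.normal(size=(n, 2))) * [1, 0.05]
    b = np.abs(rng.normal(size=(n, 2))) * [0.05, 1]
    freq = pd.DataFrame(np.vstack([a, b]), columns=["gaitA", "gaitB"])
    freq = freq.div(freq.sum(axis=1) + 1e-9, axis=0)
    res = gait_pca_group_test(freq, ["g1"] * n + ["g2"] * n)
    assert res.p_raw < 0.01


def test_gait_pca_permuted_labels_ns_on_average():
    rng = np.random.default_rng(11)
    freq = pd.DataFrame(rng.dirichlet(np.ones(4), size=40))
    rejections = 0
    for rep in range(40):
        labels = rng.permutation(["g1"] * 20 + ["g2"] * 20)
        rejections += gait_pca_group_test(freq, labels).p_raw < 0.05
    assert rejections <= 6  # ~5% nominal


def test_gait_pca_posthoc_family():
    bouts = synth.gen_study_table(synth.SynthConfig(seed=12))
    freq = bouts.groupby(["species", "gait"], observed=True).size().unstack(fill_value=0)
    freq = freq.div(freq.sum(axis=1), axis=0)
    groups = [s.rsplit("_", 1)[0] for s in freq.index]
    res = gait_pca_group_test(freq, groups)
    assert res.extra["n_components"] >= 1
    assert "posthoc" in res.extra


# ---------------------------------------------------------------------------
# Spearman correlates

def test_spearman_monotone_extremes():
    resp = pd.Series([1, 2, 3, 4, 5, 6], index=list("abcdef"), dtype=float)
    morph = pd.DataFrame({"up": resp**2, "down": -resp + 10}, index=resp.index)
    table = spearman_morph_correlates(resp, morph)
    assert table.loc["up", "rho"] == pytest.approx(1.0)
    assert table.loc["down", "rho"] == pytest.approx(-1.0)


def test_spearman_ties_match_bruteforce_ranks():
    resp = pd.Series([1.0, 2.0, 2.0, 3.0, 5.0, 4.0], index=list("abcdef"))
    var = pd.Series([2.0, 2.0, 3.0, 5.0, 5.0, 7.0], index=list("abcdef"))
    table = spearman_morph_correlates(resp, var.to_frame("v"))

    def avg_ranks(x):
        order = np.argsort(x, kind="stable")
        ranks = np.empty(len(x))
        sx = np.asarray(x)[order]
        i = 0
        while i < len(x):
            j = i
            while j + 1 < len(x) and sx[j + 1] == sx[i]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    r1, r2 = avg_ranks(resp.to_numpy()), avg_ranks(var.to_numpy())
    expected = np.corrcoef(r1, r2)[0, 1]
    assert table.loc["v", "rho"] == pytest.approx(expected, abs=1e-12)


def test_spearman_constant_variable_is_na_with_warning():
    resp = pd.Series(np.arange(6, dtype=float), index=list("abcdef"))
    morph = pd.DataFrame({"flat": np.ones(6)}, index=resp.index)
    with pytest.warns(RuntimeWarning):
        table = spearman_morph_correlates(resp, morph)
    assert np.isnan(table.loc["flat", "rho"])


def test_spearman_min_pairs_enforced():
    resp = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
    table = spearman_morph_correlates(resp, resp.to_frame("v"))
    assert np.isnan(table.loc["v", "rho"])


def test_adjust_family_monotone():
    from vertdescent.ethogram import TestResult

    results = [TestResult(0.0, p, "anova") for p in (0.01, 0.2, 0.04)]
    adjust_family(results)
    for r in results:
        assert r.p_adjusted >= r.p_raw - 1e-15
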