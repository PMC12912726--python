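"""Descent-strategy proportions and the bootstrap / rank statistics around them.

Covers: two-stage (events-within-individuals, then across-individual)
strategy proportion tables; bootstrap ANOVA/MANOVA of support-diameter
effects on strategy proportions; Mann-Whitney ascent/descent kinematic
contrasts with percent change; Wilcoxon signed-rank contrasts of the
symmetrical-gait fraction; MANOVA on PCA-reduced gait frequencies; the
Benjamini-Hochberg step-up correction; and Spearman correlations of
descent proportions against morphological variables.

Every bootstrap routine takes an explicit seed and is reproducible;
family-wise BH adjustment is applied with :func:`adjust_family` over
whatever family of tests the caller assembles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .kinematics import STRATEGIES, SUPPORTS

__all__ = [
    "TestResult",
    "tabulate_strategy_proportions",
    "bootstrap_support_effect_test",
    "kinematic_contrast",
    "gait_fraction_contrast",
    "gait_pca_group_test",
    "bh_adjust",
    "adjust_family",
    "spearman_morph_correlates",
]


@dataclass
class TestResult:
    """One hypothesis test with provenance of its resampling."""

    statistic: float
    p_raw: float
    method: str
    p_adjusted: float = float("nan")
    n_boot: int = 0
    seed: int | None = None
    extra: dict = field(default_factory=dict)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_family(results: list[TestResult]) -> list[TestResult]:
    """BH-adjust a family of test results in place (and return it)."""
    if results:
        adj = bh_adjust([r.p_raw for r in results])
        for r, a in zip(results, adj):
            r.p_adjusted = float(a)
    return results


# ---------------------------------------------------------------------------
# strategy proportions

def _individual_proportions(events: pd.DataFrame) -> pd.DataFrame:
    """Per-individual strategy proportions (%) from descent events."""
    counts = (
        events.groupby(["individual", "strategy"], observed=True).size().unstack(fill_value=0)
    )
    for s in STRATEGIES:
        if s not in counts.columns:
            counts[s] = 0
    counts = counts[list(STRATEGIES)]
    return 100.0 * counts.div(counts.sum(axis=1), axis=0)


def tabulate_strategy_proportions(bouts: pd.DataFrame) -> pd.DataFrame:
    """Species x support strategy proportions, averaged over individuals.

    Proportions are computed per individual first and then averaged
    (unweighted) across the individuals of the species, so individuals
    with many events do not dominate. Cells without descent data are
    absent (NA when reindexed).
    """
    descents = bouts[bouts["direction"] == "descent"]
    rows = []
    for (species, support), grp in descents.groupby(["species", "support"], observed=True):
        props = _individual_proportions(grp)
        rec = {"species": species, "support": support}
        rec.update(props.mean(axis=0).to_dict())
        rec["n_individuals"] = props.shape[0]
        rec["n_events"] = len(grp)
        rows.append(rec)
    table = pd.DataFrame(rows).set_index(["species", "support"])
    return table[list(STRATEGIES) + ["n_individuals", "n_events"]]


# ---------------------------------------------------------------------------
# support-diameter effect on strategy proportions

def _bootstrap_proportions(grp: pd.DataFrame, n_ind: int, n_events: int,
                           rng: np.random.Generator) -> np.ndarray:
    """n_ind resampled individuals x 3 strategy proportions for one support."""
    individuals = grp["individual"].unique()
    out = np.zeros((n_ind, len(STRATEGIES)))
    strat_codes = pd.Categorical(grp["strategy"], categories=STRATEGIES).codes
    by_ind = {ind: strat_codes[(grp["individual"] == ind).to_numpy()] for ind in individuals}
    for i, ind in enumerate(rng.choice(individuals, size=n_ind, replace=True)):
        events = rng.choice(by_ind[ind], size=n_events, replace=True)
        out[i] = 100.0 * np.bincount(events, minlength=len(STRATEGIES)) / n_events
    return out


def _anova_or_manova(responses: list[np.ndarray], n_strategies: int) -> tuple[float, float, str]:
    """Omnibus test of group differences in strategy-proportion responses.

    With two strategies in the species' repertoire the proportions are
    complementary, so a one-way ANOVA on the varying proportion is used;
    with three or more, a Wilks MANOVA on all but one proportion column
    (the columns sum to 100). Near-collinear bootstrap responses fall
    back to fewer columns, then to an ANOVA.
    """
    Y = np.vstack(responses)
    varying = [j for j in range(Y.shape[1]) if np.ptp(Y[:, j]) > 1e-12]
    if not varying or n_strategies < 2:
        return float("nan"), 1.0, "none"
    if n_strategies == 2 or len(varying) == 1:
        j = varying[0]
        stat, p = stats.f_oneway(*[r[:, j] for r in responses])
        return float(stat), float(p), "anova"
    from statsmodels.multivariate.manova import MANOVA

    cols = varying[:-1] if len(varying) == len(STRATEGIES) else varying
    groups = np.repeat(np.arange(len(responses)), [len(r) for r in responses])
    while len(cols) > 1:
        df = pd.DataFrame(Y[:, cols], columns=[f"y{i}" for i in range(len(cols))])
        df["group"] = groups.astype(str)
        lhs = " + ".join(df.columns[:-1])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mv = MANOVA.from_formula(f"{lhs} ~ C(group)", data=df).mv_test()
            wilks = mv.results["C(group)"]["stat"].loc["Wilks' lambda"]
            return float(wilks["Value"]), float(wilks["Pr > F"]), "manova-wilks"
        except (np.linalg.LinAlgError, ValueError):
            cols = cols[:-1]  # near-collinear responses: drop one and retry
    stat, p = stats.f_oneway(*[r[:, cols[0]] for r in responses])
    return float(stat), float(p), "anova"


def bootstrap_support_effect_test(
    bouts: pd.DataFrame,
    species: str,
    n_ind: int = 10,
    n_events: int = 10,
    seed: int | None = None,
    posthoc_alpha: float = 0.05,
) -> TestResult:
    """Effect of support diameter on one species' descent-strategy proportions.

    Individuals (then events within each drawn individual) are
    bootstrapped to ``n_ind`` x ``n_events`` per support category to
    even out testing power; the omnibus test is an ANOVA when one
    strategy varies and a Wilks MANOVA otherwise, with pairwise
    post hoc comparisons (BH-corrected) when the omnibus is significant.
    """
    rng = np.random.default_rng(seed)
    descents = bouts[(bouts["species"] == species) & (bouts["direction"] == "descent")]
    supports = [s for s in SUPPORTS if (descents["support"] == s).any()]
    if len(supports) < 2:
        raise ValueError(f"species {species!r} has descent data on {len(supports)} support class(es); >= 2 required")
    responses = [
        _bootstrap_proportions(descents[descents["support"] == s], n_ind, n_events, rng)
        for s in supports
    ]
    n_strategies = descents["strategy"].nunique()
    stat, p, method = _anova_or_manova(responses, n_strategies)
    extra: dict = {"supports": supports}
    if p < posthoc_alpha and len(supports) > 2:
        pairs, raw = [], []
        for a in range(len(supports)):
            for b in range(a + 1, len(supports)):
                _, pp, _ = _anova_or_manova([responses[a], responses[b]], n_strategies)
                pairs.append((supports[a], supports[b]))
                raw.append(pp)
        adj = bh_adjust(raw)
        extra["posthoc"] = {f"{a}~{b}": float(q) for (a, b), q in zip(pairs, adj)}
    return TestResult(stat, p, method, n_boot=n_ind * n_events, seed=seed, extra=extra)


# ---------------------------------------------------------------------------
# ascent/descent kinematic contrast

def kinematic_contrast(
    ascents,
    descents,
    n_each: int = 20,
    seed: int | None = None,
) -> TestResult:
    """Mann-Whitney contrast of a kinematic variable between directions.

    ``n_each`` ascent and descent events are bootstrapped (with
    replacement) and compared by a two-sided Mann-Whitney U test; the
    percent change is 100 * (mean descent - mean ascent)/mean ascent on
    the bootstrapped samples.
    """
    a = np.asarray(ascents, dtype=float)
    d = np.asarray(descents, dtype=float)
    if a.size < 1 or d.size < 1:
        raise ValueError("both directions need at least one event")
    rng = np.random.default_rng(seed)
    boot_a = rng.choice(a, size=n_each, replace=True)
    boot_d = rng.choice(d, size=n_each, replace=True)
    if np.array_equal(np.sort(boot_a), np.sort(boot_d)):
        u, p = float(n_each * n_each / 2), 1.0
    else:
        u, p = stats.mannwhitneyu(boot_d, boot_a, alternative="two-sided")
    change = 100.0 * (boot_d.mean() - boot_a.mean()) / boot_a.mean()
    return TestResult(float(u), float(p), "mann-whitney", n_boot=2 * n_each, seed=seed,
                      extra={"percent_change": float(change)})


# ---------------------------------------------------------------------------
# symmetrical-gait fraction contrast

def gait_fraction_contrast(
    bouts: pd.DataFrame,
    support: str,
    n_boot_species: int = 100,
    n_events_each: int = 10,
    seed: int | None = None,
) -> TestResult:
    """Paired Wilcoxon test of symmetrical-gait use, ascents vs descents.

    Each of ``n_boot_species`` bootstrap draws picks a species (with
    replacement) and samples ``n_events_each`` ascent and descent events
    on the given support; the paired responses are the symmetric-gait
    fractions of the two directions. All-tied differences give p = 1 by
    convention.
    """
    rng = np.random.default_rng(seed)
    sub = bouts[bouts["support"] == support]
    pools: dict = {}
    for (sp, direction), grp in sub.groupby(["species", "direction"], observed=True):
        pools.setdefault(sp, {})[direction] = grp["symmetry"].to_numpy()
    by_species = {
        sp: (p["ascent"], p["descent"])
        for sp, p in pools.items() if "ascent" in p and "descent" in p
    }
    ok_species = sorted(by_species)
    if not ok_species:
        raise ValueError(f"no species with both directions on support {support!r}")
    sym_a, sym_d = [], []
    for sp in rng.choice(ok_species, size=n_boot_species, replace=True):
        asc, desc = by_species[sp]
        sym_a.append(rng.choice(asc, size=n_events_each, replace=True).mean())
        sym_d.append(rng.choice(desc, size=n_events_each, replace=True).mean())
    diff = np.asarray(sym_d) - np.asarray(sym_a)
    if np.all(diff == 0):
        return TestResult(0.0, 1.0, "wilcoxon", n_boot=n_boot_species, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        w, p = stats.wilcoxon(diff, alternative="two-sided", zero_method="wilcox")
    return TestResult(float(w), float(p), "wilcoxon", n_boot=n_boot_species, seed=seed,
                      extra={"mean_fraction_change": float(diff.mean())})


# ---------------------------------------------------------------------------
# gait-frequency MANOVA on principal components

def gait_pca_group_test(
    freq_matrix: pd.DataFrame,
    groups,
    variance_retained: float = 0.95,
) -> TestResult:
    """Wilks MANOVA of group differences in PCA-reduced gait frequencies.

    ``freq_matrix`` rows are individual-on-support observations, columns
    gait-type frequencies. PCA (centered, not scaled) keeps the smallest
    leading component set reaching ``variance_retained`` cumulative
    variance; pairwise group post hocs are BH-corrected.
    """
    from sklearn.decomposition import PCA

    from .physignal import retained_components

    Y = freq_matrix.to_numpy(dtype=float)
    groups = np.asarray(groups)
    if groups.size != Y.shape[0]:
        raise ValueError("groups must label each row of the frequency matrix")
    pca = PCA()
    scores = pca.fit_transform(Y)
    m = retained_components(pca.explained_variance_ratio_, variance_retained)
    if Y.shape[0] <= m:
        raise ValueError(
            f"{Y.shape[0]} rows cannot support {m} retained components; "
            "pool more observations or lower the variance threshold"
        )
    scores = scores[:, :m]

    def wilks(sc, gr):
        if sc.shape[1] == 1:  # one retained component: univariate ANOVA
            gr = np.asarray(gr)
            stat, p = stats.f_oneway(*[sc[gr == g, 0] for g in pd.unique(gr)])
            return float(stat), float(p)
        df = pd.DataFrame(sc, columns=[f"pc{i}" for i in range(sc.shape[1])])
        df["group"] = np.asarray(gr).astype(str)
        lhs = " + ".join(df.columns[:-1])
        from statsmodels.multivariate.manova import MANOVA

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mv = MANOVA.from_formula(f"{lhs} ~ C(group)", data=df).mv_test()
        row = mv.results["C(group)"]["stat"].loc["Wilks' lambda"]
        return float(row["Value"]), float(row["Pr > F"])

    stat, p = wilks(scores, groups)
    labels = pd.unique(groups)
    extra: dict = {"n_components": int(m),
                   "explained_variance": float(pca.explained_variance_ratio_[:m].sum())}
    if len(labels) > 2:
        pairs, raw = [], []
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                sel = np.isin(groups, [labels[i], labels[j]])
                try:
                    _, pp = wilks(scores[sel], groups[sel])
                except Exception:
                    pp = float("nan")
                pairs.append((labels[i], labels[j]))
                raw.append(pp)
        finite = np.isfinite(raw)
        adj = np.full(len(raw), np.nan)
        if finite.any():
            adj[finite] = bh_adjust(np.asarray(raw)[finite])
        extra["posthoc"] = {f"{a}~{b}": float(q) for (a, b), q in zip(pairs, adj)}
    return TestResult(stat, p, "manova-wilks", extra=extra)


# ---------------------------------------------------------------------------
# morphological correlates

def spearman_morph_correlates(
    response: pd.Series,
    morph: pd.DataFrame,
    min_n: int = 5,
) -> pd.DataFrame:
    """Spearman correlation of each morphological variable with a response.

    ``response`` (e.g. % head-first descent per species) is joined with
    each column of ``morph`` on the index; variables with fewer than
    ``min_n`` complete pairs or zero variance yield NA (with a warning)
    and are excluded from the BH family.
    """
    rows = []
    for col in morph.columns:
        joined = pd.concat([response.rename("resp"), morph[col].rename("var")], axis=1).dropna()
        if len(joined) < min_n:
            rows.append({"variable": col, "rho": np.nan, "p_raw": np.nan, "n": len(joined)})
            continue
        if joined["var"].nunique() == 1 or joined["resp"].nunique() == 1:
            warnings.warn(f"constant values for {col!r}; correlation undefined", RuntimeWarning)
            rows.append({"variable": col, "rho": np.nan, "p_raw": np.nan, "n": len(joined)})
            continue
        rho, p = stats.spearmanr(joined["var"], joined["resp"])
        rows.append({"variable": col, "rho": float(rho), "p_raw": float(p), "n": len(joined)})
    out = pd.DataFrame(rows).set_index("variable")
    out["p_bh"] = np.nan
    tested = out["p_raw"].notna()
    if tested.any():
        out.loc[tested, "p_bh"] = bh_adjust(out.loc[tested, "p_raw"].to_numpy())
    return out
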