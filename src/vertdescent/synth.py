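"""Synthetic study generators with known ground truth.

Everything the pipeline consumes can be generated here: footfall event
tables realizing known gait archetypes, bout tables with species-level
descent-strategy probabilities and a configured descent/ascent speed
ratio, morphology matrices with a known monotone link from predictors
to head-first descent proportion plus fossil-like missingness, and
birth-death trees with grafted fossil tips.

Defaults mirror the study conditions the pipeline targets: 21 extant
species in six phylogenetic groups, ~3 individuals per species, up to
10 events per individual per support and direction, three support
diameters, a descent speed reduced to 0.7x the ascent speed, and a
34-tip tree (21 extant + 13 fossils). Every generator takes an explicit
seed and also returns its ground truth.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import dendropy
from dendropy.simulate import treesim

from . import evomodel
from .kinematics import LIMBS, STRATEGIES, SUPPORTS, GAIT_CATEGORIES, SYMMETRICAL_GAITS
from .phylo import FossilSpec, graft_fossil_tips, node_depths, tree_height

__all__ = [
    "ARCHETYPES",
    "SynthConfig",
    "make_stride_events",
    "gen_footfall_bouts",
    "gen_study_table",
    "sim_traits_on_tree",
    "gen_morph_matrix",
    "synthetic_study_tree",
    "write_study",
]

# target kinematics per gait archetype: girdle lags and mean limb phase in %
# of stride duration, stance periods in % of mean pair contact duration.
# Symmetrical archetypes sit mid-bin; asymmetrical stance targets sit well
# clear of the 10% bound/gallop cut.
ARCHETYPES: dict[str, dict] = {
    "LSLC": {"symmetric": True, "phase": 12.5},
    "LSDC": {"symmetric": True, "phase": 37.5},
    "DSDC": {"symmetric": True, "phase": 62.5},
    "DSLC": {"symmetric": True, "phase": 87.5},
    "bound": {"symmetric": False, "fore_stance": 4.0, "hind_stance": 4.0},
    "half_bound": {"symmetric": False, "fore_stance": 16.0, "hind_stance": 4.0},
    "gallop": {"symmetric": False, "fore_stance": 16.0, "hind_stance": 16.0},
}


def make_stride_events(
    category: str,
    duty_factor_pct: float = 65.0,
    stride_duration: float = 1.0,
    jitter: float = 0.0,
    rng: np.random.Generator | None = None,
    t0: float = 1.0,
) -> dict[str, tuple[float, float, float]]:
    """Event times (td, lo, next_td) per limb realizing one gait archetype.

    Construction order: fix the stride duration, place the hindlimb
    contact midpoints, derive the forelimb midpoints from the target
    limb phase (or girdle separations for asymmetrical gaits), set
    contact widths from the duty factor, then jitter the *event times*
    by uniform(-jitter, jitter) x stride duration.
    """
    spec = ARCHETYPES[category]
    if not 0 < duty_factor_pct < 100:
        raise ValueError(f"duty factor must be in (0, 100), got {duty_factor_pct}")
    T = stride_duration
    c = duty_factor_pct / 100.0 * T
    mids = {}
    mids["LH"] = t0 + 0.45 * T
    if spec["symmetric"]:
        mids["RH"] = mids["LH"] + 0.5 * T
        mids["LF"] = mids["LH"] + spec["phase"] / 100.0 * T
        mids["RF"] = mids["RH"] + spec["phase"] / 100.0 * T
    else:
        mids["RH"] = mids["LH"] + spec["hind_stance"] / 100.0 * c
        mids["LF"] = mids["LH"] + 0.70 * T
        mids["RF"] = mids["LF"] + spec["fore_stance"] / 100.0 * c
    events = {}
    rng = np.random.default_rng(rng) if jitter else None
    for limb in LIMBS:
        td = mids[limb] - 0.5 * c
        lo = mids[limb] + 0.5 * c
        nxt = td + T
        if jitter:
            td, lo, nxt = (x + rng.uniform(-jitter, jitter) * T for x in (td, lo, nxt))
        events[limb] = (td, lo, nxt)
    return events


def gen_footfall_bouts(
    n_per_archetype: int = 10,
    duty_factors: tuple[float, ...] = (55.0, 65.0, 75.0),
    jitter: float = 0.015,
    fps: float = 120.0,
    stride_duration: float = 1.0,
    seed: int | None = None,
    species: str = "Synthetica exempli",
    integer_frames: bool = True,
) -> tuple[pd.DataFrame, pd.Series]:
    """A footfall event table plus the true generating gait per bout.

    Each archetype x duty-factor combination yields ``n_per_archetype``
    jittered strides, written in the delimited footfall format (frame
    numbers at ``fps``). Returns ``(table, truth)`` with ``truth``
    indexed by bout id.
    """
    rng = np.random.default_rng(seed)
    rows, truth = [], {}
    bout_no = 0
    for category in ARCHETYPES:
        for df_pct in duty_factors:
            for _ in range(n_per_archetype):
                bout = f"b{bout_no:05d}"
                bout_no += 1
                events = make_stride_events(
                    category, df_pct, stride_duration, jitter, rng
                )
                truth[bout] = category
                for limb in LIMBS:
                    td, lo, nxt = (t * fps for t in events[limb])
                    if integer_frames:
                        td, lo, nxt = round(td), round(lo), round(nxt)
                    rows.append(
                        {
                            "species": species,
                            "individual": f"{species}-1",
                            "support": "medium",
                            "direction": "descent",
                            "strategy": "head_first",
                            "limb": limb,
                            "td_frame": td,
                            "lo_frame": lo,
                            "next_td_frame": nxt,
                            "fps": fps,
                            "distance_m": 1.0,
                            "body_length_m": 0.25,
                            "bout": bout,
                        }
                    )
    return pd.DataFrame(rows), pd.Series(truth, name="true_gait")


# ---------------------------------------------------------------------------
# study-level bout table

GROUPS = ("strepsirrhine", "platyrrhine", "scandentian", "rodent", "carnivoran", "marsupial")

# species counts per group in the emulated study
GROUP_SIZES = {"strepsirrhine": 6, "platyrrhine": 5, "scandentian": 1,
               "rodent": 3, "carnivoran": 3, "marsupial": 3}

# descent-strategy probabilities (head_first, side, tail_first) per group:
# primates split between side/tail-first strategies, everyone else is a
# head-first descender
STRATEGY_PROBS = {
    "strepsirrhine": (0.15, 0.15, 0.70),
    "platyrrhine": (0.20, 0.65, 0.15),
    "scandentian": (1.0, 0.0, 0.0),
    "rodent": (1.0, 0.0, 0.0),
    "carnivoran": (0.85, 0.05, 0.10),
    "marsupial": (1.0, 0.0, 0.0),
}

# probability of a symmetrical gait: descents favor asymmetrical gaits
SYMMETRIC_PROB = {"ascent": 0.65, "descent": 0.35}


@dataclass
class SynthConfig:
    """Study-scale generator settings (defaults = the emulated study design)."""

    seed: int | None = None
    group_sizes: dict = field(default_factory=lambda: dict(GROUP_SIZES))
    individuals_per_species: int = 3
    events_per_cell: int = 10          # per individual x support x direction
    descent_speed_factor: float = 0.7  # descent speed = ascent speed x factor
    ascent_speed_m_s: float = 0.5
    speed_cv: float = 0.25
    strategy_probs: dict = field(default_factory=lambda: dict(STRATEGY_PROBS))
    symmetric_prob: dict = field(default_factory=lambda: dict(SYMMETRIC_PROB))
    n_fossil: int = 13
    morph_noise_sd: float = 8.0        # percent-scale noise on the descent response

    def __post_init__(self) -> None:
        if self.descent_speed_factor <= 0 or self.speed_cv <= 0:
            raise ValueError("rates and dispersions must be positive")
        for probs in self.strategy_probs.values():
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError("strategy probabilities must sum to 1")

    @property
    def species_names(self) -> list[str]:
        return [
            f"{g}_{i + 1}" for g in self.group_sizes for i in range(self.group_sizes[g])
        ]

    def group_of(self, species: str) -> str:
        return species.rsplit("_", 1)[0]


def gen_study_table(config: SynthConfig | None = None) -> pd.DataFrame:
    """Bout-level study table: strategies, speeds, and gait labels.

    Species-level strategy probabilities hold in expectation; descent
    speeds are the species' ascent speed times the configured factor
    (lognormal event noise on top); gait categories are drawn from the
    direction's symmetrical/asymmetrical mix.
    """
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed)
    rows = []
    sym_cats = list(SYMMETRICAL_GAITS)
    asym_cats = [c for c in GAIT_CATEGORIES if c not in SYMMETRICAL_GAITS]
    for species in config.species_names:
        group = config.group_of(species)
        probs = np.asarray(config.strategy_probs[group], dtype=float)
        body_length = rng.uniform(0.12, 0.5)
        species_speed = config.ascent_speed_m_s * rng.lognormal(0.0, 0.2)
        for ind in range(config.individuals_per_species):
            individual = f"{species}-{ind + 1}"
            for support in SUPPORTS:
                for direction in ("ascent", "descent"):
                    mean_speed = species_speed * (
                        config.descent_speed_factor if direction == "descent" else 1.0
                    )
                    for _ in range(config.events_per_cell):
                        strategy = (
                            rng.choice(STRATEGIES, p=probs)
                            if direction == "descent" else "not_applicable"
                        )
                        sym = rng.random() < config.symmetric_prob[direction]
                        gait = rng.choice(sym_cats if sym else asym_cats)
                        speed = mean_speed * rng.lognormal(
                            -0.5 * np.log1p(config.speed_cv**2), config.speed_cv
                        )
                        distance = rng.uniform(0.5, 1.5)
                        rows.append(
                            {
                                "species": species,
                                "group": group,
                                "individual": individual,
                                "support": support,
                                "direction": direction,
                                "strategy": strategy,
                                "gait": gait,
                                "symmetry": sym,
                                "speed_m_s": speed,
                                "relative_speed_bl_s": speed / body_length,
                                "distance_m": distance,
                                "duration_s": distance / speed,
                                "body_length_m": body_length,
                            }
                        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trees and traits

def synthetic_study_tree(
    n_extant: int = 21,
    n_fossil: int = 13,
    birth: float = 0.08,
    death: float = 0.03,
    height: float = 75.0,
    seed: int | None = None,
    labels: list[str] | None = None,
):
    """A birth-death tree of extant tips with grafted fossil tips.

    The extant tree is simulated to ``n_extant`` tips, rescaled to
    ``height`` (My), then ``n_fossil`` fossil tips are attached at
    random valid stem positions with positive tip ages. Returns
    ``(tree, fossil_specs)``.
    """
    pyrng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=birth, death_rate=death, num_extant_tips=n_extant,
        rng=pyrng, is_retain_extinct_tips=False,
    )
    # the simulation stops exactly at a speciation event, leaving zero-length
    # terminal branches (and a singular VCV); let every lineage run on for a
    # tenth of the tree height before the present
    h0 = tree_height(tree)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + 0.1 * h0
    if labels is not None:
        if len(labels) != n_extant:
            raise ValueError("label count must equal n_extant")
        for leaf, lab in zip(tree.leaf_node_iter(), labels):
            leaf.taxon.label = lab
    else:
        for i, leaf in enumerate(tree.leaf_node_iter()):
            leaf.taxon.label = f"extant_{i + 1}"
    tree = evomodel.rescale_tree_height(tree, height)
    rng = np.random.default_rng(None if seed is None else seed + 1)
    specs = []
    for f in range(n_fossil):
        for _ in range(100):
            depths = node_depths(tree)
            h = max(depths[l] for l in tree.leaf_node_iter())
            candidates = [
                nd for nd in tree.preorder_node_iter()
                if nd.parent_node is not None
                and (nd.edge.length or 0) > 1e-3 * h
                and not (nd.is_leaf() and nd.taxon.label.startswith("fossil_"))
            ]
            nd = candidates[rng.integers(len(candidates))]
            node_age = h - depths[nd]
            parent_age = h - depths[nd.parent_node]
            stem_age = rng.uniform(node_age + 0.05 * (parent_age - node_age),
                                   parent_age - 0.05 * (parent_age - node_age))
            tip_age = rng.uniform(0.2, 0.9) * stem_age
            clade = tuple(sorted(l.taxon.label for l in nd.leaf_iter()))
            spec = FossilSpec(f"fossil_{f + 1}", float(tip_age),
                              clade if len(clade) > 1 else clade[0], float(stem_age))
            try:
                tree = graft_fossil_tips(tree, [spec])
                specs.append(spec)
                break
            except ValueError:
                continue
        else:
            raise RuntimeError("could not place a fossil tip after 100 attempts")
    return tree, specs


def sim_traits_on_tree(
    tree: dendropy.Tree,
    model: str,
    params: dict,
    seed: int | None = None,
    size: int = 1,
    regimes=None,
    root: str = "theta",
) -> pd.DataFrame:
    """Exact tip-trait simulation: one MVN draw per replicate.

    The mean and covariance come from the model's closed-form tip
    distribution, so the draw is exact (no per-branch discretization).
    Returns replicates x tips.
    """
    order = sorted(l.taxon.label for l in tree.leaf_node_iter())
    st = evomodel.tree_structure(tree, order, regimes=regimes)
    mean, V = evomodel.model_moments(model, params, st, root=root)
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(mean, V, size=size, method="cholesky")
    return pd.DataFrame(draws, columns=order)


# ---------------------------------------------------------------------------
# morphology matrix with fossil-like missingness

MISSINGNESS_TEMPLATES = {
    "complete": [],
    "cranial-only": ["pct_forelimb_body", "pct_hindlimb_body", "intermembral_index",
                     "pct_tail_body"],
    "postcranial-only": ["eq"],
}

# correlation structure of the six predictors (log10 body mass, EQ,
# forelimb %, hindlimb %, intermembral index, tail %): limb lengths
# correlate with each other and with EQ, hindlimb with tail
_PRED_MEANS = np.array([2.8, 1.1, 62.0, 70.0, 85.0, 85.0])
_PRED_SDS = np.array([0.6, 0.45, 9.0, 10.0, 10.0, 25.0])
_PRED_CORR = np.array(
    [
        [1.00, 0.30, 0.10, 0.10, 0.10, 0.10],
        [0.30, 1.00, 0.50, 0.50, 0.10, 0.20],
        [0.10, 0.50, 1.00, 0.70, 0.30, 0.20],
        [0.10, 0.50, 0.70, 1.00, -0.20, 0.50],
        [0.10, 0.10, 0.30, -0.20, 1.00, 0.00],
        [0.10, 0.20, 0.20, 0.50, 0.00, 1.00],
    ]
)

# signs of the monotone link from standardized predictors to head-first %:
# heavier, larger-headed, longer-limbed and longer-tailed species (and the
# low-IMI hindlimb-dominated ones) avoid head-first descents
_LINK_WEIGHTS = np.array([-0.8, -1.0, -0.6, -0.8, -0.5, -0.6])


def gen_morph_matrix(
    n_extant: int = 21,
    n_fossil: int = 13,
    noise_sd: float = 8.0,
    seed: int | None = None,
    extant_labels: list[str] | None = None,
    fossil_labels: list[str] | None = None,
    templates: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Analysis-ready morphology matrix with a known response and masking.

    Predictors are drawn from a correlated Gaussian; the head-first
    response is a monotone (sigmoidal) function of a weighted predictor
    combination plus noise, on the 0-100% scale. Fossil rows get the
    response masked plus a per-fossil missingness template
    ('complete', 'cranial-only', 'postcranial-only'). Returns
    ``(matrix, true_fossil_response)``.
    """
    rng = np.random.default_rng(seed)
    n = n_extant + n_fossil
    L = np.linalg.cholesky(_PRED_CORR)
    Z = rng.standard_normal((n, 6)) @ L.T
    X = _PRED_MEANS + Z * _PRED_SDS
    eta = Z @ _LINK_WEIGHTS / np.sqrt((_LINK_WEIGHTS**2).sum())
    response = 100.0 / (1.0 + np.exp(-1.5 * eta))
    response = np.clip(response + rng.normal(0.0, noise_sd, size=n), 0.0, 100.0)
    if extant_labels is None:
        extant_labels = [f"extant_{i + 1}" for i in range(n_extant)]
    if fossil_labels is None:
        fossil_labels = [f"fossil_{i + 1}" for i in range(n_fossil)]
    index = list(extant_labels) + list(fossil_labels)
    data = pd.DataFrame(X, columns=HEAD_FIRST_COLUMNS[:-1], index=index)
    data["head_first_pct"] = response
    truth = data.loc[fossil_labels, "head_first_pct"].copy()
    data.loc[fossil_labels, "head_first_pct"] = np.nan
    template_names = list(MISSINGNESS_TEMPLATES)
    if templates is None:
        templates = [template_names[i % len(template_names)] for i in range(n_fossil)]
    for lab, tmpl in zip(fossil_labels, templates):
        data.loc[lab, MISSINGNESS_TEMPLATES[tmpl]] = np.nan
    return data, truth


HEAD_FIRST_COLUMNS = [
    "log10_body_mass", "eq", "pct_forelimb_body", "pct_hindlimb_body",
    "intermembral_index", "pct_tail_body", "head_first_pct",
]


def write_study(outdir, seed: int | None = None, config: SynthConfig | None = None) -> dict:
    """Write a full synthetic study (footfall, bouts, morphology, tree) to disk."""
    from pathlib import Path

    from .phylo import write_newick

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config or SynthConfig(seed=seed)
    ss = np.random.SeedSequence(seed)
    s_foot, s_bouts, s_tree, s_morph = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(4))
    footfall, truth = gen_footfall_bouts(n_per_archetype=3, seed=s_foot)
    config.seed = s_bouts
    bouts = gen_study_table(config)
    species = config.species_names
    tree, specs = synthetic_study_tree(
        n_extant=len(species), n_fossil=config.n_fossil, seed=s_tree, labels=species
    )
    fossil_labels = [s.name for s in specs]
    morph, morph_truth = gen_morph_matrix(
        n_extant=len(species), n_fossil=config.n_fossil, noise_sd=config.morph_noise_sd,
        seed=s_morph, extant_labels=species, fossil_labels=fossil_labels,
    )
    paths = {
        "footfall": outdir / "footfall.csv",
        "footfall_truth": outdir / "footfall_truth.csv",
        "bouts": outdir / "bouts.csv",
        "morphology": outdir / "morphology.csv",
        "morphology_truth": outdir / "morphology_truth.csv",
        "tree": outdir / "tree.nwk",
    }
    footfall.to_csv(paths["footfall"], index=False)
    truth.rename_axis("bout").to_csv(paths["footfall_truth"])
    bouts.to_csv(paths["bouts"], index=False)
    morph.rename_axis("species").to_csv(paths["morphology"])
    morph_truth.rename_axis("species").to_csv(paths["morphology_truth"])
    write_newick(tree, paths["tree"])
    return {k: str(v) for k, v in paths.items()}
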