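import numpy as np
import pandas as pd
import pytest

from vertdescent import phylo, synth


@pytest.fixture(scope="session")
def three_tip_tree():
    return phylo.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def study_tree():
    """21 extant + 13 fossil tips, My units, the study's scale."""
    tree, specs = synth.synthetic_study_tree(n_extant=21, n_fossil=13, seed=11)
    return tree


@pytest.fixture(scope="session")
def extant_tree():
    tree, _ = synth.synthetic_study_tree(n_extant=21, n_fossil=0, seed=11)
    return tree


@pytest.fixture(scope="session")
def study_bouts():
    return synth.gen_study_table(synth.SynthConfig(seed=7))


def random_cycle(rng):
    """A random valid stride cycle (events as plain tuples per limb)."""
    from vertdescent.kinematics import LIMBS, LimbStride, StrideCycle

    T = rng.uniform(0.4, 2.0)
    strides = {}
    for limb in LIMBS:
        td = rng.uniform(0, 3)
        c = rng.uniform(0.2, 0.9) * T
        strides[limb] = LimbStride(limb, td, td + c, td + T * rng.uniform(0.9, 1.1))
    return StrideCycle(strides)
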