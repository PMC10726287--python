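"""Shared fixtures: one synthetic reference cell and compiled models.

The reference morphology (seed 1) is the study tree used throughout the
suite; compiling and the first kernel call are cached at session scope so
the numba compilation cost is paid once.
"""

import numpy as np
import pytest

from vmthal import biophysics as B
from vmthal import morphology as M
from vmthal import simulate as S


#: seed of the full-scale reference morphology: its dendritic length
#: (~5.85 mm) matches the reference length at which the published synapse
#: totals apply
REF_SEED = 2


@pytest.fixture(scope="session")
def ref_tree():
    return M.build_cell(M.synth_skeleton(REF_SEED))


@pytest.fixture(scope="session")
def normal_cell(ref_tree):
    return S.compile_cell(ref_tree, B.canonical_params("normal"))


@pytest.fixture(scope="session")
def park_cell(ref_tree):
    return S.compile_cell(ref_tree, B.canonical_params("parkinsonian"))


def make_passive_params(g_leak=50.0, r_i=150.0, v_rest=-70.0):
    """All channel densities zero: an analytically checkable passive cell."""
    p = B.canonical_params("normal")
    p.r_i = r_i
    p.v_rest = v_rest
    p.g_leak = g_leak
    for ch in p.channels.values():
        ch.g = 0.0
        ch.g_extra = 0.0
        ch.g_min = 0.0
        ch.p1 = 0.0
        ch.p2 = 0.0
    return p


def two_comp_tree(l1=24.0, d1=20.0, l2=40.0, d2=2.0):
    """Soma plus one single-compartment dendrite (no AIS pruning here)."""
    nodes = [M.SkeletonNode(0, None, "soma", 0.0),
             M.SkeletonNode(1, 0, "dendrite", l2)]
    tree = M.MorphTree(nodes)
    tree.diameters = {1: d2}
    # compile manually: soma cylinder + one dendritic compartment
    import math
    comps = [M.Compartment(0, None, l1, d1, math.pi * d1 * l1, "soma", 0.0, 0),
             M.Compartment(1, 0, l2, d2, math.pi * d2 * l2, "dend",
                           l2 / 2.0, 1)]
    tree.compartments = comps
    return tree


@pytest.fixture()
def passive_two_comp():
    tree = two_comp_tree()
    params = make_passive_params()
    return S.compile_cell(tree, params)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
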