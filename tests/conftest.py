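"""Shared fixtures: small hand-built trees and a desk-scale simulated pair."""

import warnings

import numpy as np
import pytest

from clonefate.simulator import SimulationParams, simulate_pair
from clonefate.treecore import Node, Phylogeny


@pytest.fixture
def abc_tree():
    """((A:1,B:1):2,C:3); — the classic three-leaf worked example."""
    root = Node("root")
    ab = root.add_child(Node("AB", 2.0))
    ab.add_child(Node("A", 1.0))
    ab.add_child(Node("B", 1.0))
    root.add_child(Node("C", 3.0))
    return Phylogeny(root)


@pytest.fixture
def clone_cut_tree():
    """((A:90,B:90):60,C:150); in molecular time, root = zygote."""
    root = Node("root")
    ab = root.add_child(Node("AB", 60.0))
    ab.add_child(Node("A", 90.0))
    ab.add_child(Node("B", 90.0))
    root.add_child(Node("C", 150.0))
    return Phylogeny(root)


@pytest.fixture(scope="session")
def small_pair_params():
    return SimulationParams(
        n_hsc=1500, n_trans=400, donor_age_hct=30.0, donor_age_bd=40.0,
        n_colonies_donor=60, n_colonies_recipient=60,
    )


@pytest.fixture(scope="session")
def small_pair(small_pair_params):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_pair(small_pair_params, seed=42)


def random_ultrametric_tree(rng, n_leaves: int, height: float = 100.0) -> Phylogeny:
    """Random coalescent-style ultrametric tree for property tests."""
    nodes = [Node(f"L{i}") for i in range(n_leaves)]
    heights = {n: height for n in nodes}
    counter = 0
    active = list(nodes)
    merge_heights = np.sort(rng.uniform(0, height, size=n_leaves - 1))[::-1]
    for h in merge_heights:
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[i], active[j]
        parent = Node(f"N{counter}")
        counter += 1
        a.length = heights[a] - h
        b.length = heights[b] - h
        parent.add_child(a)
        parent.add_child(b)
        heights[parent] = h
        active = [n for n in active if n not in (a, b)] + [parent]
    root = active[0]
    root.length = heights[root]
    top = Node("root")
    top.add_child(root)
    t = Phylogeny(top, unit="years")
    t.meta["ultrametric"] = True
    return t
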