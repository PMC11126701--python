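import numpy as np
import pytest

from nectarevo import mk, synth, treeio


@pytest.fixture(scope="session")
def cherry():
    return treeio.parse_newick("(A:1,B:1);")


@pytest.fixture(scope="session")
def four_tip_balanced():
    return treeio.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def bd_tree_60():
    return synth.sim_bd_tree(0.1, 0.02, stop_n=60, seed=11)


@pytest.fixture(scope="session")
def mk_sim_60(bd_tree_60):
    """60-tip tree with a simulated binary trait (ER, q = 0.05)."""
    Q = mk.build_q([0.05], 2, "ER")
    tips, hist = synth.sim_mk_traits(bd_tree_60, Q, root_state=0, seed=12)
    return bd_tree_60, tips, hist, Q


def random_small_tree(rng, n_tips):
    """Random binary tree with exponential branch lengths (not ultrametric)."""
    parent = [-1]
    lengths = [0.0]
    leaves = [0]
    while len(leaves) < n_tips:
        v = leaves.pop(rng.integers(len(leaves)))
        for _ in range(2):
            parent.append(v)
            lengths.append(float(rng.exponential(1.0)))
            leaves.append(len(parent) - 1)
    # renumber: tips first
    leaves_set = set(leaves)
    order = sorted(leaves_set) + [i for i in range(len(parent)) if i not in leaves_set]
    idx = {v: i for i, v in enumerate(order)}
    new_parent = np.full(len(parent), -1, dtype=np.int64)
    new_lengths = np.zeros(len(parent))
    for v in range(len(parent)):
        if parent[v] >= 0:
            new_parent[idx[v]] = idx[parent[v]]
            new_lengths[idx[v]] = lengths[v]
    labels = [f"t{i}" for i in range(len(leaves_set))]
    return treeio.PhyloTree(new_parent, new_lengths, labels)
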