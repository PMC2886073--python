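import numpy as np
import pytest

import phylodiv as pv


@pytest.fixture
def balanced4():
    """Balanced 4-tip tree ((A,B),(C,D));"""
    return pv.parse_newick("((A,B),(C,D));")


@pytest.fixture
def balanced4_values():
    return {"A": 0.0, "B": 2.0, "C": 4.0, "D": 6.0}


@pytest.fixture
def cherry_enlarged():
    """(A,(C,D)) with A expanded into two virtual sister-taxa."""
    tree = pv.parse_newick("(A,(C,D));")
    return pv.enlarge_with_replicates(tree, {"A": ["1", "2"]})


def standardized_tip_values(labels, values):
    z, _ = pv.standardize(values)
    return dict(zip(labels, z))


@pytest.fixture
def random_tree_factory():
    """Random topologies with polytomies, deterministic per call index."""
    from phylodiv.synthetic import collapse_random_edges, simulate_yule_topology

    def make(n_tips: int, seed: int, polytomy_prob: float = 0.3):
        tree = simulate_yule_topology(n_tips, seed)
        if polytomy_prob > 0 and n_tips > 3:
            tree = collapse_random_edges(tree, polytomy_prob, seed + 1)
        return tree

    return make
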