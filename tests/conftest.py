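import numpy as np
import pytest

from xmodnn.hierarchy import FunctionalHierarchy, HierarchyNode
from xmodnn.synthetic import SyntheticSpec, make_hierarchy, simulate


def build_hierarchy(edges, levels):
    """Hand-build a hierarchy from (child, parent) pairs and id->level map."""
    nodes = {nid: HierarchyNode(nid, lv, nid) for nid, lv in levels.items()}
    for c, p in edges:
        nodes[c].parents.add(p)
        nodes[p].children.add(c)
    return FunctionalHierarchy(nodes=nodes)


@pytest.fixture
def minimal_chain():
    """2 genes -> c1 -> b1 -> a1 -> O (6 nodes, 5 edges)."""
    levels = {"g1": "D", "g2": "D", "c1": "C", "b1": "B", "a1": "A", "O": "O"}
    edges = [("g1", "c1"), ("g2", "c1"), ("c1", "b1"), ("b1", "a1"), ("a1", "O")]
    return build_hierarchy(edges, levels)


@pytest.fixture
def two_pathway():
    """8 nodes: g1->c1, g2->c2, both C under b1 -> a1 -> O."""
    levels = {"g1": "D", "g2": "D", "c1": "C", "c2": "C", "b1": "B",
              "a1": "A", "O": "O"}
    edges = [("g1", "c1"), ("g2", "c2"), ("c1", "b1"), ("c2", "b1"),
             ("b1", "a1"), ("a1", "O")]
    return build_hierarchy(edges, levels)


@pytest.fixture
def fixture20():
    """Synthetic 20-gene / 4-C / 2-B / 1-A hierarchy with generated data."""
    spec = SyntheticSpec(n_genes=20, n_c=4, n_b=2, n_a=1,
                         n_samples=(20, 20), n_planted=4, seed=7)
    h, x, y, truth = simulate(spec)
    return spec, h, x, y, truth


def random_small_hierarchy(rng: np.random.Generator):
    """Random hierarchy with <= 50 genes for property tests."""
    spec = SyntheticSpec(
        n_genes=int(rng.integers(4, 51)),
        n_c=int(rng.integers(2, 6)),
        n_b=int(rng.integers(1, 4)),
        n_a=int(rng.integers(1, 3)),
        membership_fanout=float(rng.uniform(1.0, 1.5)),
        n_planted=1,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    h, _ = make_hierarchy(spec)
    return h


def randomize_weights(net, rng: np.random.Generator, scale=1.0):
    """Overwrite all weights with random values; biases stay as they are."""
    for p in net.modules.values():
        for l in range(len(p.W)):
            p.W[l] = rng.normal(0, scale, size=p.W[l].shape)
        p.W_head = rng.normal(0, scale, size=p.W_head.shape)
    return net
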