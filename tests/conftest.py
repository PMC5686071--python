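import numpy as np
import pytest

from opsinevo.io_formats import SpeciesTree


@pytest.fixture
def balanced4() -> SpeciesTree:
    return SpeciesTree.from_newick("((A:1.0,B:1.0):1.0,(C:1.0,D:1.0):1.0);")


@pytest.fixture
def pectinate4() -> SpeciesTree:
    return SpeciesTree.from_newick("(((A:1.0,B:1.0):1.0,C:2.0):1.0,D:3.0);")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_tree(rng: np.random.Generator, n_leaves: int, height: float = 1.0) -> SpeciesTree:
    """Random ultrametric topology by sequential coalescence of leaf labels."""
    labels = [f"L{i}" for i in range(n_leaves)]
    nodes = {lab: (lab, 0.0) for lab in labels}  # newick fragment, current depth
    active = list(labels)
    depth = 0.0
    while len(active) > 1:
        depth += float(rng.uniform(0.1, 1.0))
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        fa, da = nodes.pop(a)
        fb, db = nodes.pop(b)
        merged = f"({fa}:{depth - da},{fb}:{depth - db})"
        key = a + b
        nodes[key] = (merged, depth)
        active = [x for x in active if x not in (a, b)] + [key]
    frag, d = nodes[active[0]]
    scale = height / d if d > 0 else 1.0
    tree = SpeciesTree.from_newick(frag + ";")
    for nd in tree.dendropy_tree.preorder_node_iter():
        if nd.edge.length is not None:
            nd.edge.length *= scale
    return tree
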