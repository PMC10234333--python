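import numpy as np
import pytest
from skbio.tree import TreeNode

from stutzpan import phylo


def random_additive_matrix(n_taxa: int, rng: np.random.Generator) -> phylo.DistanceMatrix:
    """Distance matrix of a random binary tree with random branch lengths
    (additive by construction)."""
    nodes = [TreeNode(name=f"t{i}", length=float(rng.uniform(0.5, 3.0)))
             for i in range(n_taxa)]
    while len(nodes) > 1:
        a = nodes.pop(int(rng.integers(len(nodes))))
        b = nodes.pop(int(rng.integers(len(nodes))))
        parent = TreeNode(length=float(rng.uniform(0.5, 3.0)))
        parent.extend([a, b])
        nodes.append(parent)
    tree = nodes[0]
    taxa = sorted(t.name for t in tree.tips())
    return phylo.tree_distance_matrix(tree, taxa)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
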