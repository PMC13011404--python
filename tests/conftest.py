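import dendropy
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_tree(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = True
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node and edge.length is None:
            edge.length = 1.0
    return tree


@pytest.fixture
def quartet_tree():
    return make_tree("((A,B),(C,D));")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
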