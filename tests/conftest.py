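import numpy as np
import pytest
from hypothesis import settings

from pidap import AssociationMatrix, DiseaseDAG, SequenceSet, default_fixture

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixture_data():
    """The default synthetic fixture: 60 piRNAs x 12 diseases, 3 blocks."""
    return default_fixture()


@pytest.fixture
def chain_dag():
    """anchor <- parent <- grandparent <- root, one disease anchored at the bottom."""
    edges = frozenset(
        [("root", "grandparent"), ("grandparent", "parent"), ("parent", "anchor")]
    )
    nodes = frozenset(t for e in edges for t in e)
    return DiseaseDAG(nodes=nodes, edges=edges, term_map={"d1": "anchor"})


@pytest.fixture
def sibling_dag():
    """root -> parent -> {s1, s2}: two sibling anchors under one parent."""
    edges = frozenset([("root", "parent"), ("parent", "s1"), ("parent", "s2")])
    nodes = frozenset(t for e in edges for t in e)
    return DiseaseDAG(
        nodes=nodes, edges=edges, term_map={"d1": "s1", "d2": "s2", "d3": "s1"}
    )


@pytest.fixture
def tiny_assoc():
    return AssociationMatrix(
        np.array([[1, 0], [0, 1]]), ["p1", "p2"], ["d1", "d2"]
    )


@pytest.fixture
def two_block_network():
    """A 20-node similarity network with two planted blocks."""
    from pidap.similarity import SimilarityNetwork

    rng = np.random.default_rng(42)
    p = 20
    block = np.repeat([0, 1], p // 2)
    S = np.where(block[:, None] == block[None, :], 0.8, 0.1)
    S = S + rng.uniform(-0.05, 0.05, (p, p))
    S = np.clip((S + S.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    net = SimilarityNetwork(S=S, node_ids=[f"n{i}" for i in range(p)], channel="pirna_seq")
    return net, block
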