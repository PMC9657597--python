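import numpy as np
import pytest

from linkgnn.data import AssociationMatrix, PairSample, sample_negative_pairs
from linkgnn.estimator import SubgraphGNNClassifier
from linkgnn.subgraph import LabelEncoding, batch_extract
from linkgnn.synthetic import SBMSpec, fixture_graphs, generate_bipartite_sbm


@pytest.fixture(scope="session")
def fixtures():
    return fixture_graphs()


@pytest.fixture(scope="session")
def two_by_two(fixtures):
    return fixtures["two_by_two"]["matrix"]


@pytest.fixture(scope="session")
def small_sbm():
    """A small block-model graph with clear planted structure."""
    return generate_bipartite_sbm(
        SBMSpec(nm=40, nd=30, n_blocks=2, p_in=0.4, p_out=0.05, seed=7)
    )


@pytest.fixture(scope="session")
def small_subgraphs(small_sbm):
    pos = small_sbm.positive_pairs()
    neg = sample_negative_pairs(small_sbm, len(pos), seed=7)
    return batch_extract(small_sbm, pos + neg, h=2, encoding=LabelEncoding())


@pytest.fixture(scope="session")
def tiny_trained(small_subgraphs):
    """A quickly trained classifier shared by contract tests."""
    clf = SubgraphGNNClassifier(epochs=3, seed=0)
    clf.fit(small_subgraphs[:120] + small_subgraphs[-120:])
    return clf


def random_bipartite(rng, max_nodes=40, p=0.25):
    """Random bipartite association matrix for property tests."""
    nm = int(rng.integers(2, max_nodes // 2))
    nd = int(rng.integers(2, max_nodes // 2))
    Y = (rng.random((nm, nd)) < p).astype(np.uint8)
    return AssociationMatrix(
        Y, [f"m{i}" for i in range(nm)], [f"d{j}" for j in range(nd)]
    )
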