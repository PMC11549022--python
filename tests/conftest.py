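import networkx as nx
import numpy as np
import pytest

from painrank import simulate
from painrank.model import PainGeneClassifier


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-gene cohort with all planted effects at default strength."""
    return simulate.generate(simulate.SimConfig(n_genes=400, seed=17))


@pytest.fixture(scope="session")
def small_model(small_cohort):
    return PainGeneClassifier.from_cohort(small_cohort)


@pytest.fixture(scope="session")
def small_results(small_model):
    return small_model.fit(cv_folds=0)


def random_connected_graph(n: int, p: float, seed: int) -> nx.Graph:
    """Random simple graph, resampled until connected."""
    rng = np.random.default_rng(seed)
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if g.number_of_edges() and nx.is_connected(g):
            return nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
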