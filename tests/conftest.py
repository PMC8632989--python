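import random

import networkx as nx
import numpy as np
import pytest

from symdiv.data_io import AssociationRecord, AssociationTable


def random_graph(n: int, p: float, seed: int) -> nx.Graph:
    return nx.gnp_random_graph(n, p, seed=seed)


def brute_force_node_diversity(G: nx.Graph, j) -> float:
    """Independent oracle: literally enumerate, per neighbor i, the edges
    {i, u} with u outside the closed neighborhood of j."""
    closed = set(G[j]) | {j}
    total = 0.0
    for i in G[j]:
        k = G.degree(i)
        if k < 2:
            continue
        leaving = sum(1 for u in G[i] if u not in closed)
        total += leaving / (k - 1)
    return total


def make_assoc(pairs) -> AssociationTable:
    return AssociationTable(
        [AssociationRecord(p, p, g) for p, g in pairs]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def py_rng():
    return random.Random(1234)
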