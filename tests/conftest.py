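import numpy as np
import pytest

from ddiwalk.io_formats import DrugRecord, PPIEdgeList
from ddiwalk.ppi_network import build_transition_matrix


@pytest.fixture
def two_node_matrix():
    """Single edge u-v: the smallest nontrivial walk substrate."""
    return build_transition_matrix(PPIEdgeList(edges=[("u", "v", 1.0)]))


@pytest.fixture
def path_graph_matrix():
    """Path a-b-c."""
    return build_transition_matrix(
        PPIEdgeList(edges=[("a", "b", 1.0), ("b", "c", 1.0)])
    )


@pytest.fixture
def five_drugs():
    """Small drug universe with real, distinct SMILES."""
    smiles = ["CCO", "CCN", "c1ccccc1", "CC(=O)O", "CCCCO"]
    return [
        DrugRecord(f"d{i}", smi, frozenset({f"g{i}", f"g{i+1}"}))
        for i, smi in enumerate(smiles)
    ]


def random_edge_list(rng: np.random.Generator, n_nodes: int, p: float) -> PPIEdgeList:
    """Erdos-Renyi edge list, guaranteed non-empty and connected enough to use."""
    edges = []
    nodes = [f"n{i}" for i in range(n_nodes)]
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p:
                edges.append((nodes[i], nodes[j], float(rng.integers(1, 1000))))
    if not edges:
        edges = [(nodes[0], nodes[1], 1.0)]
    return PPIEdgeList(edges=edges)
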