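import networkx as nx
import numpy as np
import pandas as pd
import pytest

import chromalink as cl
from chromalink import fixtures


@pytest.fixture(scope="session")
def small_spec():
    """400-bin, 4-TAD chromosome; smallest extent the generator accepts."""
    return cl.SyntheticSpec(n_bins=400, n_tads=4, noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def noisefree_matrix(small_spec):
    return fixtures.synth_contact_matrix(small_spec)


@pytest.fixture(scope="session")
def network_fixture():
    return fixtures.synth_multi_celltype_networks(cl.SyntheticSpec(seed=7))


@pytest.fixture(scope="session")
def similarity_panel(network_fixture):
    """Adjacency matrices of the SBM graphs as clustering input."""
    sims = {}
    for ct, g in network_fixture.graphs.items():
        nodes = sorted(g.nodes)
        sims[ct] = pd.DataFrame(nx.to_numpy_array(g, nodelist=nodes),
                                index=nodes, columns=nodes)
    return sims


@pytest.fixture(scope="session")
def noisy_loops():
    """Significant interactions called on a noisy synthetic matrix."""
    spec = cl.SyntheticSpec(n_bins=400, n_tads=4, noise_sd=1.2, seed=5)
    cm, _ = fixtures.synth_contact_matrix(spec)
    return spec, cl.call_loops(cm)


def random_graph(n: int, p: float, seed: int) -> nx.Graph:
    g = nx.gnp_random_graph(n, p, seed=seed)
    g = nx.relabel_nodes(g, {i: f"n{i:03d}" for i in g.nodes})
    nx.set_edge_attributes(g, 1.0, "weight")
    return g
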