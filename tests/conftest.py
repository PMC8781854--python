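"""Shared fixtures: motif models, solenoid structures, synthetic studies."""

import numpy as np
import pytest

from ankanet.synthgen import (
    SolenoidSpec,
    ankyrin_motif,
    generate_solenoid_structure,
)

#: suite-wide seed convention
SEED = 1


@pytest.fixture(scope="session")
def motif():
    return ankyrin_motif()


@pytest.fixture(scope="session")
def solenoid_spec():
    return SolenoidSpec(n_copies=6)


@pytest.fixture(scope="session")
def solenoid(solenoid_spec):
    return generate_solenoid_structure(solenoid_spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(SEED)


def random_connected_graph(n, rng, p=0.4):
    """Random undirected graph, resampled until connected (n small)."""
    import networkx as nx

    while True:
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p:
                    g.add_edge(i, j)
        if nx.is_connected(g):
            return g
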