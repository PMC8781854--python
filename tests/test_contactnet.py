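"""Contact networks and centralities against independent oracles."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from ankanet.contactnet import (
    ContactNetwork,
    NetworkError,
    NetworkParams,
    betweenness,
    build_network,
    eigenvector_centrality,
    plddt_domain_filter,
)
from ankanet.io_formats import CaResidue, CaStructure

from conftest import SEED, random_connected_graph


def structure_from_coords(coords, plddt=None):
    return CaStructure(
        [
            CaResidue("A", i + 1, "A", *xyz,
                      plddt=None if plddt is None else plddt[i])
            for i, xyz in enumerate(coords)
        ]
    )


def network_from_graph(g):
    return ContactNetwork(sorted(g.nodes), g, NetworkParams())


# --- independent oracles ---------------------------------------------------

def brute_force_edges(coords, resnums, r_c, min_sep):
    edges = set()
    for i in range(len(coords)):
        for j in range(i + 1, len(coords)):
            d = math.dist(coords[i], coords[j])
            if d <= r_c and abs(resnums[i] - resnums[j]) >= min_sep:
                edges.add((min(resnums[i], resnums[j]), max(resnums[i], resnums[j])))
    return edges


def enumerate_betweenness(g):
    """Exhaustive geodesic enumeration (BFS + path counting by DFS)."""
    nodes = sorted(g.nodes)
    B = {u: 0.0 for u in nodes}
    for s, t in itertools.combinations(nodes, 2):
        # BFS distances from s
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in g[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        if t not in dist:
            continue
        # enumerate all geodesics s -> t by backward DFS from t
        paths = []
        stack = [(t, [t])]
        while stack:
            u, path = stack.pop()
            if u == s:
                paths.append(path)
                continue
            for v in g[u]:
                if dist.get(v, -1) == dist[u] - 1:
                    stack.append((v, path + [v]))
        for path in paths:
            for u in path[1:-1]:
                B[u] += 1.0 / len(paths)
    return B


# --- build_network ---------------------------------------------------------

class TestBuildNetwork:
    def test_edge_at_cutoff_boundary(self):
        near = structure_from_coords([(0, 0, 0), (6.9, 0, 0)])
        far = structure_from_coords([(0, 0, 0), (7.1, 0, 0)])
        assert build_network(near).edges() == [(1, 2)]
        assert build_network(far).edges() == []

    def test_collinear_chain_degrees(self):
        coords = [(3.8 * i, 0, 0) for i in range(5)]
        net = build_network(structure_from_coords(coords))
        degrees = [net.degree()[u] for u in net.nodes]
        assert degrees == [1, 2, 2, 2, 1]

    def test_min_sep_excludes_backbone_neighbors(self):
        coords = [(3.8 * i, 0, 0) for i in range(5)]
        net = build_network(
            structure_from_coords(coords), params=NetworkParams(7.0, 2)
        )
        assert net.edges() == []

    def test_region_selection(self, solenoid):
        net = build_network(solenoid, region=[(1, 33)])
        assert net.nodes == list(range(1, 34))

    def test_empty_selection_rejected(self, solenoid):
        with pytest.raises(NetworkError):
            build_network(solenoid, region=[(10_000, 10_001)])

    def test_adjacency_invariants(self, solenoid):
        net = build_network(solenoid)
        A = net.adjacency_matrix()
        assert np.array_equal(A, A.T)
        assert np.all(np.diag(A) == 0)
        assert A.sum() == 2 * net.graph.number_of_edges()

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(SEED)
        coords = rng.uniform(0, 30, size=(60, 3))
        structure = structure_from_coords(coords)
        for r_c, min_sep in [(5.0, 1), (7.0, 2), (9.0, 1)]:
            net = build_network(structure, params=NetworkParams(r_c, min_sep))
            expected = brute_force_edges(coords, structure.resnums(), r_c, min_sep)
            assert set(net.edges()) == expected


# --- betweenness -----------------------------------------------------------

class TestBetweenness:
    def test_path_graph(self):
        g = nx.path_graph(3)
        B = betweenness(network_from_graph(g))
        assert B == {0: 0.0, 1: 1.0, 2: 0.0}

    def test_complete_graph_all_zero(self):
        B = betweenness(network_from_graph(nx.complete_graph(4)))
        assert all(v == 0.0 for v in B.values())

    def test_star_center(self):
        B = betweenness(network_from_graph(nx.star_graph(3)))
        assert B[0] == 3.0

    def test_disconnected_pairs_contribute_zero(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (2, 3)])
        B = betweenness(network_from_graph(g))
        assert all(v == 0.0 for v in B.values())

    def test_matches_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(SEED)
        for _ in range(40):
            g = random_connected_graph(int(rng.integers(4, 13)), rng)
            B = betweenness(network_from_graph(g))
            oracle = enumerate_betweenness(g)
            for u in g.nodes:
                assert B[u] == pytest.approx(oracle[u], abs=1e-9)


# --- eigenvector centrality ------------------------------------------------

class TestEigenvector:
    def test_complete_graph_uniform(self):
        res = eigenvector_centrality(network_from_graph(nx.complete_graph(5)))
        assert res.eigenvalue == pytest.approx(4.0)
        assert all(v == pytest.approx(1.0) for v in res.values.values())

    def test_path_graph_closed_form(self):
        res = eigenvector_centrality(network_from_graph(nx.path_graph(3)))
        assert res.eigenvalue == pytest.approx(math.sqrt(2), abs=1e-9)
        assert res.values[1] == pytest.approx(1.0)
        assert res.values[0] == pytest.approx(1 / math.sqrt(2), abs=1e-8)
        assert res.values[2] == pytest.approx(1 / math.sqrt(2), abs=1e-8)

    def test_fixed_point_equation_holds(self, solenoid):
        net = build_network(solenoid)
        res = eigenvector_centrality(net)
        A = net.adjacency_matrix()
        x = np.array([res.values[u] for u in net.nodes])
        assert np.linalg.norm(A @ x - res.eigenvalue * x, ord=np.inf) < 1e-8

    def test_matches_dense_eigensolver(self):
        rng = np.random.default_rng(SEED)
        for _ in range(40):
            g = random_connected_graph(int(rng.integers(4, 13)), rng)
            res = eigenvector_centrality(network_from_graph(g))
            A = nx.to_numpy_array(g, nodelist=sorted(g.nodes))
            w, v = np.linalg.eigh(A)
            lead = np.abs(v[:, -1])
            lead /= lead.max()
            assert res.eigenvalue == pytest.approx(w[-1], abs=1e-8)
            for i, u in enumerate(sorted(g.nodes)):
                assert res.values[u] == pytest.approx(lead[i], abs=1e-8)

    def test_nodes_outside_largest_component_get_zero(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (3, 4)])
        res = eigenvector_centrality(network_from_graph(g))
        assert res.values[3] == 0.0 and res.values[4] == 0.0
        assert res.values[1] == pytest.approx(1.0)

    def test_edgeless_graph_rejected(self):
        g = nx.Graph()
        g.add_nodes_from([0, 1])
        with pytest.raises(NetworkError):
            eigenvector_centrality(network_from_graph(g))

    def test_bipartite_graph_converges(self):
        # star graphs have eigenvalues +/- sqrt(n); the shift keeps the
        # Perron direction dominant
        res = eigenvector_centrality(network_from_graph(nx.star_graph(4)))
        assert res.eigenvalue == pytest.approx(2.0, abs=1e-9)
        assert res.values[0] == pytest.approx(1.0)


# --- pLDDT filter ----------------------------------------------------------

class TestPlddtFilter:
    def test_high_confidence_passes(self):
        s = structure_from_coords([(0, 0, 0), (3.8, 0, 0)], plddt=[95, 95])
        ok, mean = plddt_domain_filter(s)
        assert ok and mean == 95.0

    def test_mixed_confidence_fails(self):
        s = structure_from_coords(
            [(3.8 * i, 0, 0) for i in range(4)], plddt=[100, 100, 79, 79]
        )
        ok, mean = plddt_domain_filter(s)
        assert not ok and mean == pytest.approx(89.5)

    def test_boundary_mean_passes(self):
        s = structure_from_coords([(0, 0, 0), (3.8, 0, 0)], plddt=[90, 90])
        ok, _ = plddt_domain_filter(s, cutoff=90)
        assert ok

    def test_empty_region_rejected(self):
        s = structure_from_coords([(0, 0, 0)], plddt=[95])
        with pytest.raises(NetworkError):
            plddt_domain_filter(s, region=[(5, 6)])

    def test_isolated_node_centralities(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2)])
        g.add_node(9)
        net = network_from_graph(g)
        assert net.degree()[9] == 0
        assert betweenness(net)[9] == 0.0
        assert eigenvector_centrality(net).values[9] == 0.0
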