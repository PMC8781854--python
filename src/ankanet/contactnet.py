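"""Calpha contact networks and node centralities.

A protein structure is reduced to an unweighted graph: residues (Calpha
atoms) are nodes, and an edge joins residues i, j whenever their Euclidean
distance is at most the cutoff R_c (default 7 A) and their sequence
separation |i - j| is at least ``min_sep`` (default 1, i.e. only self-pairs
are excluded).  Degree, betweenness (unnormalized, over unordered pairs)
and eigenvector centrality (principal eigenvector of the adjacency matrix,
scaled to unit maximum) are computed on that graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .io_formats import CaStructure


class NetworkError(ValueError):
    """Raised for empty selections or degenerate centrality requests."""


@dataclass(frozen=True)
class NetworkParams:
    r_c: float = 7.0
    min_sep: int = 1

    def __post_init__(self) -> None:
        if self.r_c <= 0:
            raise ValueError("r_c must be positive")
        if self.min_sep < 1:
            raise ValueError("min_sep must be >= 1")


@dataclass
class ContactNetwork:
    """Symmetric 0/1 residue graph with its construction parameters.

    Nodes are residue numbers (ints) of one chain, kept in sequence order in
    ``nodes``; the adjacency lives in a networkx Graph.
    """

    nodes: list[int]
    graph: nx.Graph
    params: NetworkParams
    chain: str = "A"

    @property
    def n(self) -> int:
        return len(self.nodes)

    def edges(self) -> list[tuple[int, int]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges())

    def degree(self) -> dict[int, int]:
        return {u: self.graph.degree(u) for u in self.nodes}

    def adjacency_matrix(self) -> np.ndarray:
        return nx.to_numpy_array(self.graph, nodelist=self.nodes)


def _select_region(
    structure: CaStructure, region: Optional[Sequence[tuple[int, int]]]
):
    if region is None:
        return list(structure.residues)
    chosen = [
        r for r in structure.residues
        if any(s <= r.resnum <= e for s, e in region)
    ]
    return chosen


def build_network(
    structure: CaStructure,
    region: Optional[Sequence[tuple[int, int]]] = None,
    params: NetworkParams = NetworkParams(),
) -> ContactNetwork:
    """Build the contact network of a structure (optionally a residue region).

    ``region`` is a list of 1-based inclusive residue-number ranges (e.g. the
    annotated repeat domain).  The k-d tree is an exact accelerator: the edge
    set equals an all-pairs distance scan.
    """
    residues = _select_region(structure, region)
    if not residues:
        raise NetworkError("empty residue selection")
    nums = [r.resnum for r in residues]
    coords = np.array([[r.x, r.y, r.z] for r in residues])

    graph = nx.Graph()
    graph.add_nodes_from(nums)
    tree = cKDTree(coords)
    for i, j in tree.query_pairs(params.r_c):
        if abs(nums[i] - nums[j]) >= params.min_sep:
            graph.add_edge(nums[i], nums[j])
    return ContactNetwork(nums, graph, params, chain=residues[0].chain)


def betweenness(network: ContactNetwork) -> dict[int, float]:
    """Unnormalized betweenness over unordered node pairs.

    B(u) = sum over pairs {s,t}, s != t != u, of the fraction of s-t
    geodesics passing through u; pairs in different components contribute 0.
    """
    if network.n < 1:
        raise NetworkError("network has no nodes")
    return dict(nx.betweenness_centrality(network.graph, normalized=False))


@dataclass
class EigenResult:
    values: dict[int, float]
    eigenvalue: float


def eigenvector_centrality(
    network: ContactNetwork, tol: float = 1e-10, max_iter: int = 10000
) -> EigenResult:
    """Principal-eigenvector centrality, scaled so the maximum entry is 1.

    Computed on the largest connected component by shifted power iteration
    (iterating A + I keeps the Perron direction dominant on bipartite
    graphs); nodes outside that component get 0.  The fixed point
    x_i = (1/lambda) * sum_j A_ij x_j is verified to 10*tol*lambda in the
    infinity norm before returning.
    """
    if network.graph.number_of_edges() == 0:
        raise NetworkError("eigenvector centrality is degenerate on an edgeless graph")
    components = sorted(nx.connected_components(network.graph), key=len, reverse=True)
    comp = sorted(components[0])
    A = nx.to_numpy_array(network.graph, nodelist=comp)

    x = np.ones(len(comp))
    x /= np.linalg.norm(x)
    lam = 0.0
    for _ in range(max_iter):
        y = A @ x + x  # (A + I) x
        y_norm = np.linalg.norm(y)
        y /= y_norm
        if np.linalg.norm(y - x, ord=np.inf) < tol:
            x = y
            break
        x = y
    lam = float(x @ (A @ x))  # Rayleigh quotient on A itself
    residual = np.linalg.norm(A @ x - lam * x, ord=np.inf)
    if residual > 10 * tol * max(lam, 1.0):
        raise NetworkError(
            f"power iteration did not converge: residual {residual:.2e}"
        )
    x = np.abs(x)
    x /= x.max()
    values = {u: 0.0 for u in network.nodes}
    values.update({u: float(v) for u, v in zip(comp, x)})
    return EigenResult(values, lam)


def plddt_domain_filter(
    structure: CaStructure,
    region: Optional[Sequence[tuple[int, int]]] = None,
    cutoff: float = 90.0,
) -> tuple[bool, float]:
    """Mean-pLDDT confidence gate over a residue region (``>= cutoff`` passes)."""
    residues = _select_region(structure, region)
    if not residues:
        raise NetworkError("empty region for pLDDT filter")
    values = [r.plddt for r in residues]
    if any(v is None for v in values):
        raise NetworkError("structure carries no pLDDT values")
    mean = float(np.mean([float(v) for v in values]))
    return mean >= cutoff, mean
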