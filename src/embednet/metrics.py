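"""Per-node embeddedness metrics and per-network topology descriptors.

The directed measures (out-degree, k-shell-out index, betweenness) quantify
a node's downstream reach; the small-world index normalizes clustering and
path length by Erdős–Rényi references at matched size and density. Clustering
and path length are computed on the undirected projection of the graph, as in
the small-world literature; the directed measures stay directed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import networkx as nx
import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .netgen import DirectedNetwork, generate_er_network


@dataclass
class EmbeddednessProfile:
    """Per-node structural metrics; arrays are indexed by node id."""

    out_degree: np.ndarray
    k_shell_out: np.ndarray
    betweenness: np.ndarray | None = None

    def __post_init__(self):
        if np.any(self.k_shell_out > self.out_degree):
            raise ValueError("k_shell_out may not exceed out_degree")


class PathLengthResult(NamedTuple):
    """Mean shortest path over reachable ordered pairs in the giant component."""

    length: float
    n_excluded_pairs: int

    def __float__(self) -> float:
        return self.length


@dataclass
class SmallWorldResult:
    clustering: float
    path_length: float
    clustering_rand: float
    path_length_rand: float
    swi: float
    n_references: int


def out_degree(network: DirectedNetwork) -> np.ndarray:
    """Number of distinct edges leaving each node."""
    return network.out_degrees()


def k_shell_out(network: DirectedNetwork) -> np.ndarray:
    """Directed k-core decomposition on out-degree.

    For k = 1, 2, ... iteratively delete every node whose out-degree within
    the surviving subgraph is < k until stable; a node's index is the largest
    k for which it survives (nodes removed in the k = 1 sweep get 0). The
    result is independent of deletion order.
    """
    n = network.n_nodes
    deg = network.out_degrees().astype(np.int64)
    # in-adjacency (predecessors), CSR over post
    order = np.argsort(network.edges[:, 1], kind="stable")
    pre_sorted = network.edges[order, 0]
    post_counts = np.bincount(network.edges[:, 1], minlength=n)
    indptr = np.concatenate([[0], np.cumsum(post_counts)])

    shell = np.zeros(n, dtype=np.int64)
    alive = np.ones(n, dtype=bool)
    k = 1
    frontier = list(np.flatnonzero(deg < k))
    n_alive = n
    while n_alive:
        while frontier:
            next_frontier = []
            for v in frontier:
                if not alive[v]:
                    continue
                alive[v] = False
                shell[v] = k - 1
                n_alive -= 1
                for u in pre_sorted[indptr[v]:indptr[v + 1]]:
                    if alive[u]:
                        deg[u] -= 1
                        if deg[u] < k:
                            next_frontier.append(u)
            frontier = next_frontier
        k += 1
        frontier = list(np.flatnonzero(alive & (deg < k)))
    return shell


def k_shell_out_bruteforce(network: DirectedNetwork) -> np.ndarray:
    """Literal repeated subgraph-minimum-out-degree pruning (test oracle)."""
    n = network.n_nodes
    shell = np.zeros(n, dtype=np.int64)
    alive = np.ones(n, dtype=bool)
    edges = network.edges
    k = 1
    while alive.any():
        changed = True
        while changed:
            changed = False
            mask = alive[edges[:, 0]] & alive[edges[:, 1]]
            deg = np.bincount(edges[mask, 0], minlength=n)
            kill = alive & (deg < k)
            if kill.any():
                shell[kill] = k - 1
                alive[kill] = False
                changed = True
        k += 1
    return shell


def _undirected_csr(network: DirectedNetwork):
    e = network.edges
    n = network.n_nodes
    data = np.ones(2 * len(e), dtype=np.int8)
    rows = np.concatenate([e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0]])
    m = coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    m.data[:] = 1
    return m


def clustering_coefficient(network: DirectedNetwork) -> float:
    """Average local clustering coefficient of the undirected projection.

    Returns 0.0 (with a warning) when no node has degree >= 2.
    """
    if network.n_nodes < 3:
        raise ValueError("clustering requires at least 3 nodes")
    g = nx.Graph()
    g.add_nodes_from(range(network.n_nodes))
    g.add_edges_from(map(tuple, network.edges.tolist()))
    if max(dict(g.degree()).values(), default=0) < 2:
        import warnings

        warnings.warn("degenerate graph: all nodes have degree < 2")
        return 0.0
    return float(nx.average_clustering(g))


def average_shortest_path(network: DirectedNetwork) -> PathLengthResult:
    """Mean shortest-path length over ordered pairs of the giant component
    of the undirected projection; pairs outside it are excluded and counted.
    """
    if network.n_edges == 0:
        raise ValueError("average shortest path undefined on an edgeless graph")
    adj = _undirected_csr(network)
    n_comp, labels = connected_components(adj, directed=False)
    sizes = np.bincount(labels)
    giant = np.argmax(sizes)
    members = np.flatnonzero(labels == giant)
    sub = adj[np.ix_(members, members)]
    dist = shortest_path(sub, method="D", unweighted=True, directed=False)
    m = len(members)
    total = dist.sum() - np.trace(dist)
    n_pairs = m * (m - 1)
    n_excluded = network.n_nodes * (network.n_nodes - 1) - n_pairs
    return PathLengthResult(float(total / n_pairs), int(n_excluded))


def small_world_index(
    network: DirectedNetwork, n_references: int = 10, seed: int = 0
) -> SmallWorldResult:
    """SWI = (C / C_r) / (L / L_r) with C_r, L_r averaged over ER references
    preserving node and directed-edge counts.
    """
    if n_references < 1:
        raise ValueError("n_references must be >= 1")
    c = clustering_coefficient(network)
    ell = average_shortest_path(network).length
    ss = np.random.SeedSequence(seed)
    c_refs, l_refs = [], []
    for i, child in enumerate(ss.spawn(n_references)):
        ref_seed = int(child.generate_state(1)[0] % (2**31))
        ref = generate_er_network(network.n_nodes, network.n_edges, seed=ref_seed)
        c_ref = clustering_coefficient(ref)
        if c_ref == 0 or ref.n_edges == 0:
            raise ValueError("degenerate ER reference graph (zero clustering)")
        c_refs.append(c_ref)
        l_refs.append(average_shortest_path(ref).length)
    c_r = float(np.mean(c_refs))
    l_r = float(np.mean(l_refs))
    return SmallWorldResult(
        clustering=c,
        path_length=ell,
        clustering_rand=c_r,
        path_length_rand=l_r,
        swi=(c / c_r) / (ell / l_r),
        n_references=n_references,
    )


def betweenness_centrality(network: DirectedNetwork) -> np.ndarray:
    """Unnormalized shortest-path betweenness on the directed graph."""
    g = network.to_networkx()
    bc = nx.betweenness_centrality(g, normalized=False)
    return np.array([bc[v] for v in range(network.n_nodes)], dtype=float)


def embeddedness_profile(
    network: DirectedNetwork, include_betweenness: bool = False
) -> EmbeddednessProfile:
    return EmbeddednessProfile(
        out_degree=out_degree(network),
        k_shell_out=k_shell_out(network),
        betweenness=betweenness_centrality(network) if include_betweenness else None,
    )
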