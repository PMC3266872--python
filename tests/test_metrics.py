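"""Embeddedness metrics against brute-force oracles and closed forms."""

import numpy as np
import pytest

from embednet import metrics, netgen
from embednet.netgen import DirectedNetwork

from conftest import random_digraph


def complete_digraph(n):
    edges = [(i, j) for i in range(n) for j in range(n) if i != j]
    return DirectedNetwork(n, np.array(edges), np.zeros(n, dtype=np.int8))


def chain(n):
    edges = [(i, i + 1) for i in range(n - 1)]
    return DirectedNetwork(n, np.array(edges), np.zeros(n, dtype=np.int8))


class TestOutDegree:
    def test_toy_node5(self, toy):
        assert metrics.out_degree(toy)[4] == 8

    def test_isolated_node_and_edge_sum(self):
        net = DirectedNetwork(4, [[0, 1], [0, 2]], np.zeros(4, dtype=np.int8))
        deg = metrics.out_degree(net)
        assert deg[3] == 0
        assert deg.sum() == net.n_edges

    def test_er_mean(self):
        net = netgen.generate_er_network(100, 990, seed=0)
        assert metrics.out_degree(net).mean() == pytest.approx(9.9)


class TestKShellOut:
    def test_complete_digraph(self):
        assert np.all(metrics.k_shell_out(complete_digraph(4)) == 3)

    def test_directed_chain_collapses(self):
        # removing the sink cascades: every node ends with shell index 0
        assert np.all(metrics.k_shell_out(chain(3)) == 0)

    def test_toy_ranking(self, toy):
        ks = metrics.k_shell_out(toy)
        assert ks[0] > ks[4]  # node 1 above node 5

    def test_bounded_by_out_degree(self, toy):
        assert np.all(metrics.k_shell_out(toy) <= metrics.out_degree(toy))

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            net = random_digraph(rng, n_max=30)
            assert np.array_equal(metrics.k_shell_out(net),
                                  metrics.k_shell_out_bruteforce(net))

    def test_monotone_under_edge_removal(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            net = random_digraph(rng, n_min=8, n_max=25, p_min=0.15)
            before = metrics.k_shell_out(net)
            drop = int(rng.integers(net.n_edges))
            thinned = DirectedNetwork(
                net.n_nodes, np.delete(net.edges, drop, axis=0),
                net.node_kind)
            after = metrics.k_shell_out(thinned)
            assert np.all(after <= before)


class TestClusteringAndPaths:
    def test_complete_graph_clustering(self):
        assert metrics.clustering_coefficient(complete_digraph(5)) == 1.0

    def test_tree_clustering(self):
        tree = DirectedNetwork(7, [(0, 1), (0, 2), (1, 3), (1, 4), (2, 5),
                                   (2, 6)], np.zeros(7, dtype=np.int8))
        assert metrics.clustering_coefficient(tree) == 0.0

    def test_ring_lattice_closed_form(self):
        # each node linked to its 4 nearest neighbours: C = 0.5
        n, half = 20, 2
        edges = [(i, (i + d) % n) for i in range(n) for d in range(1, half + 1)]
        net = DirectedNetwork(n, np.array(edges), np.zeros(n, dtype=np.int8))
        assert metrics.clustering_coefficient(net) == pytest.approx(0.5)

    def test_degenerate_graph_warns(self):
        net = DirectedNetwork(3, [[0, 1]], np.zeros(3, dtype=np.int8))
        with pytest.warns(UserWarning, match="degenerate"):
            assert metrics.clustering_coefficient(net) == 0.0

    def test_complete_graph_path_length(self):
        assert metrics.average_shortest_path(complete_digraph(5)).length == 1.0

    def test_path_graph_average(self):
        res = metrics.average_shortest_path(chain(3))
        assert res.length == pytest.approx(4.0 / 3.0)
        assert res.n_excluded_pairs == 0

    def test_er_path_length_asymptotic(self):
        net = netgen.generate_er_network(500, 2500, seed=2)
        got = metrics.average_shortest_path(net).length
        # undirected projection of 2500 arcs: mean degree ~10
        expect = np.log(500) / np.log(10)
        assert abs(got - expect) / expect < 0.10

    def test_edgeless_graph_rejected(self):
        empty = DirectedNetwork(4, np.empty((0, 2), int),
                                np.zeros(4, dtype=np.int8))
        with pytest.raises(ValueError):
            metrics.average_shortest_path(empty)


class TestSmallWorldIndex:
    def test_er_self_normalizes(self):
        net = netgen.generate_er_network(500, 5000, seed=4)
        res = metrics.small_world_index(net, n_references=5, seed=0)
        assert abs(res.swi - 1.0) < 0.15

    def test_watts_strogatz_is_small_world(self):
        import networkx as nx

        ws = nx.watts_strogatz_graph(500, 10, 0.05, seed=1)
        edges = np.array([(u, v) for u, v in ws.edges()]
                         + [(v, u) for u, v in ws.edges()])
        net = DirectedNetwork(500, edges, np.zeros(500, dtype=np.int8))
        res = metrics.small_world_index(net, n_references=5, seed=0)
        assert res.swi > 1.0

    def test_swi_is_ratio_of_normalized_metrics(self):
        net = netgen.generate_er_network(200, 2000, seed=5)
        res = metrics.small_world_index(net, n_references=3, seed=1)
        assert res.swi == pytest.approx(
            (res.clustering / res.clustering_rand)
            / (res.path_length / res.path_length_rand))

    def test_invariant_under_relabeling(self):
        rng = np.random.default_rng(21)
        net = random_digraph(rng, n_min=60, n_max=60, p_min=0.1, p_max=0.1)
        perm = rng.permutation(net.n_nodes)
        relabeled = DirectedNetwork(
            net.n_nodes, perm[net.edges], net.node_kind[np.argsort(perm)])
        a = metrics.small_world_index(net, n_references=4, seed=3)
        b = metrics.small_world_index(relabeled, n_references=4, seed=3)
        assert a.clustering == pytest.approx(b.clustering)
        assert a.path_length == pytest.approx(b.path_length)
        assert a.swi == pytest.approx(b.swi)


class TestBetweenness:
    def test_star_center_maximal(self):
        center_edges = [(0, i) for i in range(1, 6)] + [(i, 0) for i in range(1, 6)]
        net = DirectedNetwork(6, np.array(center_edges), np.zeros(6, dtype=np.int8))
        bc = metrics.betweenness_centrality(net)
        assert bc[0] == bc.max() and bc[0] > 0

    def test_complete_digraph_all_zero(self):
        assert np.all(metrics.betweenness_centrality(complete_digraph(5)) == 0)

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(31)
        for _ in range(5):
            net = random_digraph(rng, n_min=10, n_max=15, p_min=0.15, p_max=0.3)
            assert np.allclose(metrics.betweenness_centrality(net),
                               _betweenness_bruteforce(net))


def _betweenness_bruteforce(net):
    """All-pairs shortest-path enumeration by BFS path counting."""
    n = net.n_nodes
    succ = [[] for _ in range(n)]
    for p, q in net.edges:
        succ[p].append(q)
    bc = np.zeros(n)
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            paths = _all_shortest_paths(succ, n, s, t)
            if not paths:
                continue
            for path in paths:
                for v in path[1:-1]:
                    bc[v] += 1.0 / len(paths)
    return bc


def _all_shortest_paths(succ, n, s, t):
    from collections import deque

    dist = {s: 0}
    queue = deque([s])
    while queue:
        u = queue.popleft()
        for w in succ[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                queue.append(w)
    if t not in dist:
        return []
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(list(path))
            return
        for w in succ[u]:
            if w in dist and dist[w] == dist[u] + 1 and dist[w] <= dist[t]:
                path.append(w)
                extend(path)
                path.pop()

    extend([s])
    return paths


def test_profile_has_all_nodes(toy):
    prof = metrics.embeddedness_profile(toy, include_betweenness=True)
    assert len(prof.out_degree) == 14
    assert len(prof.k_shell_out) == 14
    assert len(prof.betweenness) == 14
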