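"""Generators: determinism, density calibration, ER degeneracy, fixtures,
serialization round-trips."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

from embednet import netgen
from embednet.netgen import (DirectedNetwork, GeneratingMeasure,
                             NetworkFormatError, build_modular_hub_network,
                             build_toy_network, generate_er_network,
                             generate_multifractal_network, read_network,
                             write_network)

UNIFORM = GeneratingMeasure([[0.5, 0.5], [0.5, 0.5]], [0.5, 0.5], 2)
HETERO = GeneratingMeasure([[0.9, 0.1], [0.1, 0.9]], [0.3, 0.7], 3)


class TestGeneratingMeasure:
    def test_lengths_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            GeneratingMeasure([[0.5, 0.5], [0.5, 0.5]], [0.6, 0.6], 2)

    def test_probabilities_bounded(self):
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            GeneratingMeasure([[1.5, 0.5], [0.5, 0.5]], [0.5, 0.5], 2)

    def test_refinement_blowup_rejected(self):
        with pytest.raises(ValueError, match="refined intervals"):
            GeneratingMeasure([[0.5, 0.5], [0.5, 0.5]], [0.5, 0.5], 40)

    def test_refined_lengths_and_probs(self):
        lengths, probs = HETERO.refined()
        assert lengths.shape == (8,)
        assert probs.shape == (8, 8)
        assert np.isclose(lengths.sum(), 1.0)
        # first refined interval is the triple-(category 0) cell
        assert np.isclose(lengths[0], 0.3**3)
        assert np.isclose(probs[0, 0], 0.9**3)
        assert np.isclose(probs[0, -1], 0.1**3)


class TestDirectedNetwork:
    def test_rejects_self_loops(self):
        with pytest.raises(ValueError, match="self-loop"):
            DirectedNetwork(3, [[0, 0]], np.zeros(3, dtype=np.int8))

    def test_rejects_duplicate_edges(self):
        with pytest.raises(ValueError, match="duplicate"):
            DirectedNetwork(3, [[0, 1], [0, 1]], np.zeros(3, dtype=np.int8))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError, match="out of range"):
            DirectedNetwork(3, [[0, 5]], np.zeros(3, dtype=np.int8))


class TestMultifractal:
    def test_determinism(self):
        a = generate_multifractal_network(HETERO, 200, 10.0, seed=5)
        b = generate_multifractal_network(HETERO, 200, 10.0, seed=5)
        assert np.array_equal(a.edges, b.edges)
        assert a == b

    def test_density_calibration(self):
        """Mean realized edge count within 5% of n * target_mean_degree."""
        counts = [generate_multifractal_network(HETERO, 400, 12.0, seed=s).n_edges
                  for s in range(20)]
        assert abs(np.mean(counts) - 400 * 12.0) / (400 * 12.0) < 0.05

    def test_uniform_measure_degenerates_to_er(self):
        """A flat generating measure reproduces ER out-degree statistics
        (pooled two-sample KS over 20 pairs)."""
        mf_deg, er_deg = [], []
        for s in range(20):
            mf = generate_multifractal_network(UNIFORM, 300, 10.0, seed=s)
            er = generate_er_network(300, mf.n_edges, seed=1000 + s)
            mf_deg.append(mf.out_degrees())
            er_deg.append(er.out_degrees())
        stat = ks_2samp(np.concatenate(mf_deg), np.concatenate(er_deg))
        assert stat.pvalue > 0.01

    def test_heterogeneous_measure_exceeds_er_variance(self):
        """Unequal interval lengths concentrate out-edges on one category:
        out-degree variance is well above the binomial ER value."""
        ratios = []
        for s in range(5):
            net = generate_multifractal_network(HETERO, 1000, 20.0, seed=s)
            p = 20.0 / 999
            ratios.append(net.out_degrees().var() / (999 * p * (1 - p)))
        assert np.mean(ratios) > 2.0

    def test_inhibitory_fraction(self):
        net = generate_multifractal_network(HETERO, 1000, 10.0,
                                            inh_fraction=0.2, seed=0)
        assert len(net.inhibitory) == 200
        assert len(net.excitatory) == 800

    def test_overconcentrated_measure_raises(self):
        sharp = GeneratingMeasure([[1.0, 0.0], [0.0, 0.0]], [0.5, 0.5], 2)
        with pytest.raises(ValueError, match="scale factor"):
            generate_multifractal_network(sharp, 300, 60.0, seed=0)

    def test_invalid_density(self):
        with pytest.raises(ValueError, match="target_mean_degree"):
            generate_multifractal_network(UNIFORM, 10, 9.5, seed=0)


class TestER:
    def test_zero_edges(self):
        assert generate_er_network(10, 0, seed=0).n_edges == 0

    def test_exact_edge_count_and_mean_degree(self):
        net = generate_er_network(100, 990, seed=3)
        assert net.n_edges == 990
        assert net.out_degrees().mean() == pytest.approx(9.9)

    def test_matched_control_preserves_counts(self):
        mf = generate_multifractal_network(HETERO, 300, 8.0, seed=2)
        er = netgen.matched_er_network(mf, seed=7)
        assert er.n_nodes == mf.n_nodes
        assert er.n_edges == mf.n_edges
        assert np.array_equal(er.node_kind, mf.node_kind)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            generate_er_network(5, 21, seed=0)

    def test_determinism(self):
        a = generate_er_network(50, 200, seed=9)
        b = generate_er_network(50, 200, seed=9)
        assert np.array_equal(a.edges, b.edges)


class TestModularHub:
    def test_default_scale_and_id_layout(self, hub_network):
        net = hub_network
        assert net.n_nodes == 900
        assert len(net.excitatory) == 700
        assert len(net.inhibitory) == 200
        # displayed 1-based: excitatory 1-700, inhibitory 701-900
        assert np.array_equal(net.excitatory, np.arange(700))
        assert np.array_equal(net.inhibitory, np.arange(700, 900))
        assert len(net.gen_meta["small_nodes"]) == 150

    def test_no_feedback_from_small_subnetwork(self, hub_network):
        small = set(hub_network.gen_meta["small_nodes"])
        outside = [(p, q) for p, q in hub_network.edges
                   if p in small and q not in small]
        assert outside == []

    def test_small_nodes_reachable_from_hubs_only_forward(self, hub_network):
        import networkx as nx

        g = hub_network.to_networkx()
        small = set(hub_network.gen_meta["small_nodes"])
        hubs = hub_network.gen_meta["hub_nodes"]
        reachable = set()
        for h in hubs:
            reachable |= nx.descendants(g, h)
        assert small <= reachable
        # nothing in the large subnetwork is reachable from the small one
        large = set(hub_network.gen_meta["large_nodes"])
        from_small = set()
        for s in small:
            from_small |= nx.descendants(g, s)
        assert not (from_small & large)

    def test_inconsistent_sizes_rejected(self):
        with pytest.raises(ValueError):
            build_modular_hub_network(n_small=-1)
        with pytest.raises(ValueError):
            build_modular_hub_network(n_hubs=10_000)


class TestToyNetwork:
    def test_printed_out_targets(self, toy):
        succ = {v: set() for v in range(14)}
        for p, q in toy.edges:
            succ[p].add(q + 1)
        assert succ[4] == {7, 8, 9, 10, 11, 12, 13, 14}  # node 5
        assert succ[0] == {2, 3, 4, 6}  # node 1
        for sink in range(6, 14):  # nodes 7-14
            assert succ[sink] == set()

    def test_idempotent(self, toy):
        assert build_toy_network() == toy


class TestSerialization:
    @pytest.mark.parametrize("fmt", ["tsv", "graphml"])
    def test_roundtrip_identity(self, toy, hub_network, tmp_path, fmt):
        for net in (toy, hub_network):
            path = tmp_path / f"net.{fmt}"
            write_network(net, path, fmt)
            back = read_network(path, fmt)
            assert back == net

    def test_hub_graphml_counts(self, hub_network, tmp_path):
        path = tmp_path / "hub.graphml"
        write_network(hub_network, path, "graphml")
        back = read_network(path)
        assert back.n_nodes == 900
        assert back.n_edges == hub_network.n_edges

    def test_self_loop_rejected_on_read(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("# nodes=3\n0\t0\n")
        with pytest.raises(NetworkFormatError, match="self-loop"):
            read_network(path)

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("# nodes=3\n0\t1\nnot-an-edge\n")
        with pytest.raises(NetworkFormatError, match=":3"):
            read_network(path)

    def test_unknown_kind_rejected(self, toy, tmp_path):
        path = tmp_path / "net.graphml"
        write_network(toy, path, "graphml")
        text = path.read_text().replace(">E<", ">X<", 1)
        path.write_text(text)
        with pytest.raises(NetworkFormatError, match="kind"):
            read_network(path)


def test_default_ensemble_spec_shape():
    specs = netgen.default_ensemble_spec(n_networks=12, n_er_controls=3)
    kinds = [s["kind"] for s in specs]
    assert kinds.count("multifractal") == 12
    assert kinds.count("er") == 3
    net = netgen.realize_spec(specs[0])
    assert net.n_nodes == specs[0]["n_nodes"]
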