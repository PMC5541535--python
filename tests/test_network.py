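import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from troopmove.direction import CoefSummary, InfluenceFit
from troopmove.network import (
    InfluenceNetwork,
    alpha_centrality,
    build_influence_network,
    d_core,
    node_strengths,
    permutation_null,
    weighted_kshell,
)


def _fit(focal, beta):
    dummy = CoefSummary(0.0, -1.0, 1.0)
    return InfluenceFit(
        focal=focal,
        beta={k: CoefSummary(*v) for k, v in beta.items()},
        beta_cm=dummy, beta_prev=dummy, sigma=dummy,
        pointwise_loglik=np.zeros((2, 2)), n_steps=1, seed=0,
    )


class TestScreening:
    def test_interval_excluding_zero_is_kept(self):
        fits = [_fit("i", {"j": (0.05, 0.02, 0.09)}), _fit("j", {})]
        net = build_influence_network(fits)
        assert net.graph.has_edge("j", "i")
        assert net.graph["j"]["i"]["weight"] == pytest.approx(0.05)

    def test_interval_containing_zero_is_dropped(self):
        fits = [_fit("i", {"j": (0.02, -0.01, 0.04)}), _fit("j", {})]
        assert build_influence_network(fits).graph.number_of_edges() == 0

    def test_negative_interval_becomes_repulsion_edge(self):
        fits = [_fit("i", {"j": (-0.05, -0.08, -0.02)}), _fit("j", {})]
        net = build_influence_network(fits)
        rep = net.repulsion
        assert rep["j"]["i"]["weight"] == pytest.approx(0.05)  # magnitude stored
        assert net.graph["j"]["i"]["sign"] == -1
        assert net.attraction.number_of_edges() == 0


class TestStrengths:
    def test_in_and_out_sums(self):
        net = InfluenceNetwork.from_edges(
            "ABC", [("A", "B", 0.5), ("C", "B", 0.3)]
        )
        s = node_strengths(net)
        assert s["B"] == (pytest.approx(0.8), 0.0)
        assert s["A"] == (0.0, pytest.approx(0.5))

    def test_empty_graph_all_zero(self):
        s = node_strengths(InfluenceNetwork.from_edges("AB", []))
        assert all(v == (0.0, 0.0) for v in s.values())

    def test_total_in_equals_total_out(self):
        rng = np.random.default_rng(0)
        edges = [(f"n{a}", f"n{b}", rng.uniform(0.1, 1)) for a, b in
                 [(0, 1), (1, 2), (2, 0), (3, 1)]]
        s = node_strengths(InfluenceNetwork.from_edges([f"n{i}" for i in range(4)], edges))
        tot_in = sum(v[0] for v in s.values())
        tot_out = sum(v[1] for v in s.values())
        assert tot_in == pytest.approx(tot_out)


class TestAlphaCentrality:
    def test_zero_adjacency_returns_exogenous(self):
        net = InfluenceNetwork.from_edges("AB", [])
        assert alpha_centrality(net, alpha=0.5) == {"A": 1.0, "B": 1.0}

    def test_single_edge_closed_form(self):
        net = InfluenceNetwork.from_edges("AB", [("A", "B", 0.7)])
        x = alpha_centrality(net, alpha=0.2)
        assert x["A"] == pytest.approx(1.0)
        assert x["B"] == pytest.approx(1.0 + 0.2 * 0.7)

    def test_three_node_chain_matches_hand_solution(self):
        # A -> B (w1), B -> C (w2): x_A = 1, x_B = 1 + a w1, x_C = 1 + a w2 x_B
        net = InfluenceNetwork.from_edges("ABC", [("A", "B", 0.5), ("B", "C", 0.4)])
        a = 0.3
        x = alpha_centrality(net, alpha=a)
        xb = 1 + a * 0.5
        assert x["B"] == pytest.approx(xb)
        assert x["C"] == pytest.approx(1 + a * 0.4 * xb)


def brute_force_core_numbers(g: nx.Graph) -> dict:
    """Classic k-core by direct iterative deletion, independent of the package."""
    core = {v: 0 for v in g.nodes}
    k, h = 1, g.copy()
    while h.number_of_nodes():
        changed = True
        while changed:
            low = [v for v in h.nodes if h.degree(v) < k]
            changed = bool(low)
            h.remove_nodes_from(low)
        for v in h.nodes:
            core[v] = k
        k += 1
    return core


class TestWeightedKShell:
    def test_unit_triangle_equals_classic_core(self):
        net = InfluenceNetwork.from_edges("ABC", [("A", "B", 1), ("B", "C", 1), ("C", "A", 1)])
        dec = weighted_kshell(net)
        assert all(v == pytest.approx(2.0) for v in dec.shell.values())

    def test_unit_path_equals_classic_core(self):
        net = InfluenceNetwork.from_edges("ABC", [("A", "B", 1), ("B", "C", 1)])
        dec = weighted_kshell(net)
        assert all(v == pytest.approx(1.0) for v in dec.shell.values())

    def test_isolated_node_shell_zero(self):
        net = InfluenceNetwork.from_edges("ABC", [("A", "B", 1)])
        assert weighted_kshell(net).shell["C"] == 0.0

    def test_heavy_core_reaches_sqrt_eight(self):
        # final-core nodes with degree 2 and strength 4 get shell sqrt(8) ~ 2.83
        net = InfluenceNetwork.from_edges(
            "ABC", [("A", "B", 2), ("B", "C", 2), ("C", "A", 2)]
        )
        dec = weighted_kshell(net)
        assert all(v == pytest.approx(np.sqrt(8), abs=1e-9) for v in dec.shell.values())

    def test_matches_brute_force_on_random_orientations(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(3, 11))
            und = nx.gnp_random_graph(n, rng.uniform(0.1, 0.7), seed=int(rng.integers(1e6)))
            edges = [(u, v, 1.0) if rng.random() < 0.5 else (v, u, 1.0) for u, v in und.edges]
            net = InfluenceNetwork.from_edges(range(n), edges)
            dec = weighted_kshell(net)
            expect = brute_force_core_numbers(und)
            for v in range(n):
                assert dec.shell[v] == pytest.approx(expect[v], abs=1e-9)


class TestDCore:
    def test_hand_enumerated_values(self):
        assert d_core(np.array([0.0, 0.0, 1.0, 1.0])) == 8.0
        assert d_core(np.array([0.0, 1.0, 3.0])) == 12.0
        assert d_core(np.array([2.0, 2.0])) == 0.0

    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=12),
           st.floats(-10, 10), st.floats(0.1, 5))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_translation_invariance_and_linear_scaling(self, xs, shift, scale):
        x = np.array(xs)
        base = d_core(x)
        assert d_core(x + shift) == pytest.approx(base, rel=1e-9, abs=1e-7)
        assert d_core(scale * x) == pytest.approx(scale * base, rel=1e-9, abs=1e-7)


class TestPermutationNull:
    def test_complete_graph_with_equal_weights_cannot_exceed(self):
        nodes = "ABCD"
        edges = [(u, v, 0.5) for u in nodes for v in nodes if u != v]
        res = permutation_null(InfluenceNetwork.from_edges(nodes, edges), n_perm=50, seed=0)
        assert np.allclose(res.null_d, res.observed_d)
        assert not res.exceeds

    def test_deterministic_given_seed(self):
        net = InfluenceNetwork.from_edges(
            "ABCDE", [("A", "B", 0.9), ("B", "C", 0.4), ("A", "C", 0.8), ("D", "E", 0.1)]
        )
        r1 = permutation_null(net, n_perm=25, seed=3)
        r2 = permutation_null(net, n_perm=25, seed=3)
        assert np.array_equal(r1.null_d, r2.null_d)

    def test_q95_and_exceeds_consistent(self):
        net = InfluenceNetwork.from_edges(
            "ABCDEF", [("A", "B", 1.0), ("B", "A", 1.0), ("A", "C", 0.9), ("C", "A", 0.8)]
        )
        res = permutation_null(net, n_perm=200, seed=1)
        assert res.q95 == pytest.approx(float(np.quantile(res.null_d, 0.95)))
        assert res.exceeds == (res.observed_d > res.q95)

    def test_saturated_pair_space_gives_constant_null(self):
        # 2 nodes, both ordered pairs occupied: every draw is the same graph
        net = InfluenceNetwork.from_edges("AB", [("A", "B", 1.0), ("B", "A", 0.5)])
        res = permutation_null(net, n_perm=20, seed=0)
        assert np.allclose(res.null_d, res.observed_d)
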