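"""Graph data model, family constructors, temperature, and edge-list I/O."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from moranamp import (ANParams, GraphValidationError, NodeLookupError,
                      WeightedGraph, make_amplifier_AN, make_bd_chunk,
                      make_complete, make_fan, make_star,
                      random_connected_weighted_graph, read_edge_list,
                      temperature, temperature_vector, weighted_degree,
                      write_edge_list)


class TestValidation:
    def test_rejects_tiny_population(self):
        with pytest.raises(GraphValidationError):
            WeightedGraph(["a"], [])

    @pytest.mark.parametrize(
        "edges",
        [
            [("a", "a", 1.0)],                       # self-loop
            [("a", "b", 1.0), ("b", "a", 2.0)],      # duplicate edge
            [("a", "b", 0.0)],                       # zero weight
            [("a", "b", -1.0)],                      # negative weight
            [("a", "b", float("nan"))],              # non-finite weight
            [("a", "c", 1.0)],                       # unknown endpoint
        ],
    )
    def test_rejects_bad_edges(self, edges):
        with pytest.raises(GraphValidationError):
            WeightedGraph(["a", "b"], edges)

    def test_rejects_isolated_node(self):
        with pytest.raises(GraphValidationError):
            WeightedGraph(["a", "b", "c"], [("a", "b", 1.0)])

    def test_weight_symmetry_and_connectivity_recorded(self):
        G = WeightedGraph(["a", "b", "c", "d"],
                          [("a", "b", 2.5), ("c", "d", 0.1)])
        assert G.weight("a", "b") == G.weight("b", "a") == 2.5
        assert not G.is_connected
        with pytest.raises(GraphValidationError):
            temperature(G, "a")

    def test_unknown_node_lookup(self):
        G = make_complete(3)
        with pytest.raises(NodeLookupError):
            G.weighted_degree("nope")


class TestFamilies:
    @pytest.mark.parametrize("N", [3, 11])
    def test_complete_graph_shape(self, N):
        G = make_complete(N)
        assert G.N == N and G.num_edges == N * (N - 1) // 2
        assert all(w == 1.0 for _, _, w in G.edges())
        assert weighted_degree(G, G.nodes[0]) == N - 1

    def test_complete_rejects_degenerate_size(self):
        with pytest.raises(GraphValidationError):
            make_complete(1)

    def test_star_shape(self):
        G = make_star(11)
        assert G.num_edges == 10
        assert weighted_degree(G, "center") == 10
        assert all(weighted_degree(G, leaf) == 1 for leaf in G.nodes[1:])

    def test_two_node_star_equals_complete(self):
        s, k = make_star(2), make_complete(2)
        assert s.N == k.N == 2 and s.num_edges == k.num_edges == 1

    def test_fan_shape_and_center_weight(self):
        G = make_fan(5, hub_coupling=0.01)
        assert G.N == 11 and G.num_edges == 15
        assert math.isclose(weighted_degree(G, "fan-center"), 10 * 0.01)

    def test_single_blade_fan_is_triangle(self):
        G = make_fan(1, hub_coupling=0.3)
        assert G.N == 3 and G.num_edges == 3
        assert sorted(w for _, _, w in G.edges()) == [0.3, 0.3, 1.0]

    def test_fan_rejects_zero_blades(self):
        with pytest.raises(GraphValidationError):
            make_fan(0)


class TestAmplifierAN:
    def test_fig_sizes(self):
        assert ANParams(a=5, b=5, f=11).N == 26
        assert ANParams(a=30, b=85, f=801).N == 1001

    @pytest.mark.parametrize("bad", [dict(a=0, b=1, f=3), dict(a=1, b=0, f=3),
                                     dict(a=1, b=1, f=4), dict(a=1, b=1, f=1),
                                     dict(a=1, b=1, f=3, t=1.0)])
    def test_invalid_params(self, bad):
        with pytest.raises(GraphValidationError):
            ANParams(**bad)

    @pytest.mark.parametrize("params", [ANParams(5, 5, 11, 100.0),
                                        ANParams(1, 2, 5, 10.0),
                                        ANParams(3, 1, 7, 40.0)])
    def test_weight_contract(self, params):
        """Connecting edge t^-3; u's other edges total t^-1; v's total 1."""
        G = make_amplifier_AN(params)
        u, v = G.designated["u"], G.designated["v"]
        t = params.t
        w_e = G.weight(u, v)
        assert math.isclose(w_e, t**-3, rel_tol=1e-12)
        assert abs((G.weighted_degree(u) - w_e) - 1 / t) < 1e-12
        assert abs((G.weighted_degree(v) - w_e) - 1.0) < 1e-12
        # ratio of connecting edge to u's other weight is t^-2 by construction
        assert math.isclose(w_e / (G.weighted_degree(u) - w_e), t**-2, rel_tol=1e-9)
        assert G.is_connected and G.N == params.N

    def test_bd_chunk_shape(self):
        G = make_bd_chunk(5, 5, coupling=0.01)
        assert G.N == 15
        # hub clique + blade internals + complete hub-blade bipartite couplings
        assert G.num_edges == 10 + 5 + 50


class TestTemperature:
    def test_complete_graph_is_isothermal(self):
        G = make_complete(7)
        assert np.allclose(temperature_vector(G), 1.0)

    def test_star_center_runs_hot(self):
        G = make_star(11)
        assert math.isclose(temperature(G, "center"), 10.0)
        assert math.isclose(temperature(G, "leaf-3"), 0.1)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=30, deadline=None)
    def test_temperatures_sum_to_population_size(self, seed):
        """Sum of T(u) over nodes equals N on any connected weighted graph."""
        rng = np.random.default_rng(seed)
        N = int(rng.integers(3, 9))
        G = random_connected_weighted_graph(
            N, edge_density=float(rng.uniform(0, 1)), seed=seed)
        assert math.isclose(temperature_vector(G).sum(), N, rel_tol=1e-12)


class TestEdgeListIO:
    @pytest.mark.parametrize("G", [make_complete(5), make_star(6),
                                   make_fan(3, 0.01),
                                   make_amplifier_AN(ANParams(2, 2, 5, 50.0))])
    def test_round_trip_preserves_weights_exactly(self, G, tmp_path):
        p = tmp_path / "g.tsv"
        write_edge_list(G, p)
        H = read_edge_list(p)
        assert set(H.nodes) == set(G.nodes)
        for u, v, w in G.edges():
            assert H.weight(u, v) == w  # bit-for-bit

    def test_reader_rejects_malformed_input(self, tmp_path):
        for text in ["a\tb\n", "a\tb\t0\n", "a\ta\t1\n", "a\tb\t1\na\tb\t1\n",
                     "a\tb\tx\n"]:
            p = tmp_path / "bad.tsv"
            p.write_text("# comment\n" + text + "b\tc\t1.0\n")
            with pytest.raises(GraphValidationError):
                read_edge_list(p)

    def test_comments_and_blank_lines_ignored(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("# header\n\na\tb\t1.5\n\nb\tc\t2.0\n")
        G = read_edge_list(p)
        assert G.N == 3 and G.weight("a", "b") == 1.5
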