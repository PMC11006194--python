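"""Closed forms, first-step bias, trichotomies, classification, and the
chunk-coupling model."""

import math

import numpy as np
import pytest

from moranamp import (ANParams, ChunkCouplingInputs, ProcessSpec,
                      approximate_an_fixation, chunk_coupling_approximation,
                      classify, gamma_bd_closed_form, gamma_db_closed_form,
                      gamma_first_step, gamma_first_step_mc, make_amplifier_AN,
                      make_complete, make_fan, make_star,
                      neutral_fixation_closed_form,
                      random_connected_weighted_graph, rho_complete,
                      scan_fitness_grid, solve_fixation_exact,
                      solve_fixation_lumped, neutral_start_trichotomy, first_step_trichotomy)

R_GRID_11 = [round(1.01 + 0.01 * i, 2) for i in range(10)]


class TestRhoComplete:
    @pytest.mark.parametrize("kind", ["Bd", "dB"])
    def test_neutral_limit_is_one_over_n(self, kind):
        assert rho_complete(17, 1.0, kind) == pytest.approx(1 / 17, rel=1e-14)
        # continuity at the removable singularity
        assert rho_complete(17, 1.0 + 1e-9, kind) == pytest.approx(1 / 17, rel=1e-6)

    def test_bd_formula_value(self):
        assert math.isclose(rho_complete(11, 1.1, "Bd"),
                            (1 - 1 / 1.1) / (1 - 1.1 ** -11), rel_tol=1e-14)

    def test_db_bd_cross_identity(self):
        """rho_dB(K_N) = ((N-1)/N) rho_Bd(K_{N-1}) for all N >= 3 and r."""
        for N in (3, 5, 11, 50, 200):
            for r in (0.5, 0.9, 1.0, 1.1, 1.7, 3.0):
                assert math.isclose(rho_complete(N, r, "dB"),
                                    (N - 1) / N * rho_complete(N - 1, r, "Bd"),
                                    rel_tol=1e-12)


class TestGamma:
    @pytest.mark.parametrize("N", [3, 6, 11])
    def test_complete_graph_bd_baseline(self, N):
        for r in (1.0, 1.2, 2.0):
            g = gamma_first_step(make_complete(N), "v0", ProcessSpec("Bd", r))
            assert math.isclose(g.gamma, r / (r + 1), rel_tol=1e-12)

    def test_regular_graph_bd_baseline(self):
        import networkx as nx

        from moranamp import WeightedGraph

        G = WeightedGraph.from_networkx(nx.cycle_graph(8))
        g = gamma_first_step(G, "0", ProcessSpec("Bd", 1.3))
        assert math.isclose(g.gamma, 1.3 / 2.3, rel_tol=1e-12)

    def test_complete_db_neutral_is_half(self):
        g = gamma_first_step(make_complete(9), "v0", ProcessSpec("dB", 1.0))
        assert math.isclose(g.gamma, 0.5, rel_tol=1e-12)

    @pytest.mark.parametrize("kind", ["Bd", "dB"])
    def test_closed_forms_match_generic_computation(self, random_graphs, kind):
        closed = gamma_bd_closed_form if kind == "Bd" else gamma_db_closed_form
        for G in random_graphs(8, max_n=8, seed=17):
            for u in G.nodes:
                for r in (1.0, 1.25, 1.8):
                    g = gamma_first_step(G, u, ProcessSpec(kind, r))
                    assert math.isclose(g.gamma, closed(G, u, r), abs_tol=1e-12)

    def test_mc_frequencies_match(self, random_graphs):
        for i, G in enumerate(random_graphs(3, max_n=7, seed=23)):
            g = gamma_first_step(G, G.nodes[0], ProcessSpec("Bd", 1.2))
            p, se = gamma_first_step_mc(G, G.nodes[0], ProcessSpec("Bd", 1.2),
                                        replicates=20000, seed=i)
            assert abs(p - g.gamma) < 4 * max(se, 1e-4)


class TestNeutralClosedForms:
    def test_star_leaf_db_value(self):
        """Unweighted star on 4 nodes: leaf degree 1 over total degree 6."""
        G = make_star(4)
        assert math.isclose(neutral_fixation_closed_form(G, "leaf-0", "dB"), 1 / 6)

    def test_complete_graph_symmetric(self):
        G = make_complete(8)
        for kind in ("Bd", "dB"):
            assert math.isclose(neutral_fixation_closed_form(G, "v3", kind), 1 / 8)


class TestTrichotomies:
    def test_complete_graph_is_the_equality_case(self):
        G = make_complete(6)
        assert neutral_start_trichotomy(G, "v0") == "both-equal"
        assert first_step_trichotomy(G, "v0", 1.3) == "both-equal"

    def test_star_leaf_neutral_branch(self):
        """Star N=4 leaf: dB value 1/6 < 1/4 while Bd value exceeds 1/4."""
        G = make_star(4)
        assert neutral_start_trichotomy(G, "leaf-0") == "dB-below"
        assert neutral_fixation_closed_form(G, "leaf-0", "Bd") > 1 / 4

    def test_hot_node_lands_in_bd_below(self):
        G = make_star(9)
        assert first_step_trichotomy(G, "center", 1.2) == "Bd-below"

    def test_regular_graph_first_step_bd_equality(self):
        """On a regular graph the Bd first-step survival equals r/(r+1)
        exactly; the dB side still depends on the common degree (a cycle
        sits strictly below the complete graph), so the branch is dB-below."""
        import networkx as nx

        from moranamp import WeightedGraph

        G = WeightedGraph.from_networkx(nx.cycle_graph(6))
        g = gamma_first_step(G, "0", ProcessSpec("Bd", 1.4))
        assert math.isclose(g.gamma, 1.4 / 2.4, rel_tol=1e-12)
        assert first_step_trichotomy(G, "0", 1.4) == "dB-below"

    @pytest.mark.parametrize("r", [1.0, 1.1, 1.5])
    def test_no_violations_on_random_sweep(self, random_graphs, r):
        for G in random_graphs(40, max_n=8, seed=int(r * 1000)):
            for v in G.nodes:
                neutral_start_trichotomy(G, v)   # raises on violation
                first_step_trichotomy(G, v, r)


class TestClassify:
    def test_complete_graph_is_equivalent_to_itself(self):
        v = classify(make_complete(8), ProcessSpec("Bd", 1.3))
        assert v.verdict == "equivalent"

    def test_star_verdicts_flip_between_processes(self):
        S11 = make_star(11)
        assert classify(S11, ProcessSpec("Bd", 1.05)).verdict == "amplifier"
        assert classify(S11, ProcessSpec("dB", 1.05)).verdict == "suppressor"

    def test_fan_verdicts_flip_between_processes(self):
        F11 = make_fan(5, hub_coupling=0.01)
        assert classify(F11, ProcessSpec("dB", 1.05)).verdict == "amplifier"
        assert classify(F11, ProcessSpec("Bd", 1.05)).verdict == "suppressor"

    def test_monte_carlo_verdict_carries_confidence(self):
        v = classify(make_complete(6), ProcessSpec("Bd", 1.01), method="mc",
                     replicates=500, seed=1)
        assert v.verdict == "inconclusive"
        assert v.std_error is not None


class TestScan:
    def test_complete_graph_ratio_is_identically_one(self):
        df = scan_fitness_grid(make_complete(6), "Bd", [1.01, 1.05, 1.1])
        assert np.allclose(df["ratio"], 1.0, atol=1e-9)

    def test_rho_complete_increases_with_r(self):
        vals = [rho_complete(11, r, "Bd") for r in R_GRID_11]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_grid_must_be_sorted_and_nonempty(self):
        G = make_complete(4)
        with pytest.raises(ValueError):
            scan_fitness_grid(G, "Bd", [])
        with pytest.raises(ValueError):
            scan_fitness_grid(G, "Bd", [1.1, 1.0])


class TestChunkCoupling:
    @staticmethod
    def _inputs(**over):
        base = dict(p_half_bd=0.2, p_half_db=0.2,
                    mig_mut_from_bd=1e-4, mig_res_into_bd=1e-4,
                    inv_mut_into_db=0.3, inv_res_into_bd=0.3,
                    mig_mut_from_db=1e-4, mig_res_into_db=1e-4,
                    inv_mut_into_bd=0.3, inv_res_into_db=0.3)
        base.update(over)
        return ChunkCouplingInputs(**base)

    def test_symmetric_inputs_give_fair_gamblers_ruin(self):
        res = chunk_coupling_approximation(self._inputs())
        assert math.isclose(res.p_fix_given_half_bd, 0.5, rel_tol=1e-12)
        assert math.isclose(res.fixation_probability, 0.2, rel_tol=1e-12)

    def test_upstream_chunk_dominates_at_large_separation(self):
        """With migration ratio t, fixation from half-done tends to 1."""
        prev = 0.0
        for t in (10.0, 1e3, 1e6):
            res = chunk_coupling_approximation(
                self._inputs(mig_mut_from_bd=1e-4 * t))
            assert res.p_fix_given_half_bd > prev
            prev = res.p_fix_given_half_bd
        assert prev > 1 - 1e-5

    def test_rejects_nonpositive_rates(self):
        with pytest.raises(ValueError):
            self._inputs(mig_mut_from_bd=0.0)

    @pytest.mark.parametrize("kind", ["Bd", "dB"])
    def test_approximation_tracks_exact_lumped_solution(self, kind):
        """Coarse model vs exact lumped solve on the 26-node instance at
        r=1.1: within the stated factor-2 slack (observed much closer)."""
        params = ANParams(5, 5, 11, 100.0)
        spec = ProcessSpec(kind, 1.1)
        approx, _ = approximate_an_fixation(params, spec)
        exact = solve_fixation_lumped(make_amplifier_AN(params), spec).probability
        ratio = approx.fixation_probability / exact
        assert 0.5 < ratio < 2.0

    @pytest.mark.parametrize("kind,expect_forward", [("Bd", True), ("dB", False)])
    def test_migration_asymmetry_flips_with_update_rule(self, kind, expect_forward):
        """Offspring flow along the connecting edge runs u->v under Bd and
        v->u under dB (ratio about t)."""
        params = ANParams(5, 5, 11, 100.0)
        _, inputs = approximate_an_fixation(params, ProcessSpec(kind, 1.1))
        fwd, bwd = inputs.mig_mut_from_bd, inputs.mig_res_into_bd
        if expect_forward:
            assert fwd > 10 * bwd
        else:
            assert bwd > 10 * fwd
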