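"""Engine tests: polynomial mechanics, oracle equivalence, linearization."""

import numpy as np
import pytest

from sigreach import (
    EngineError,
    ProbabilisticNetwork,
    ReachabilityEngine,
    ValidationError,
    XYPolynomial,
    brute_force_reachability,
    collapse,
    fixture,
    linear_coefficients,
    multiply_edge,
    reachability,
    reachability_matrix,
)

from conftest import random_instance


def series_net():
    return fixture("series")


class TestMultiplyEdge:
    def test_first_multiplication_splits_identity(self):
        poly = multiply_edge(XYPolynomial.empty(), 0, 0.7)
        assert poly.terms[frozenset({0})] == pytest.approx(0.7)
        assert poly.terms[frozenset()] == pytest.approx(0.3)
        assert poly.processed == {0}

    def test_free_terms_absorb_both_outcomes(self):
        poly = XYPolynomial(processed=frozenset({0}), terms={}, b=0.4, c=0.6)
        out = multiply_edge(poly, 1, 0.9)
        assert out.b == 0.4 and out.c == 0.6 and not out.terms

    def test_two_multiplications_give_four_terms(self):
        poly = multiply_edge(XYPolynomial.empty(), 0, 0.5)
        poly = multiply_edge(poly, 1, 0.5)
        assert len(poly.terms) == 4
        assert all(a == pytest.approx(0.25) for a in poly.terms.values())

    def test_remultiplying_edge_is_an_error(self):
        poly = multiply_edge(XYPolynomial.empty(), 0, 0.5)
        with pytest.raises(EngineError):
            multiply_edge(poly, 0, 0.5)


class TestCollapse:
    def test_full_path_moves_to_reached(self):
        net = series_net()
        poly = multiply_edge(multiply_edge(XYPolynomial.empty(), 0, 0.5), 1, 0.5)
        out = collapse(poly, net, "s", "t")
        assert out.b == pytest.approx(0.25)  # both edges present
        assert out.c == pytest.approx(0.75)  # any absence cuts a series chain
        assert not out.terms

    def test_absent_edge_cut_moves_to_cut(self):
        net = series_net()
        poly = multiply_edge(XYPolynomial.empty(), 0, 0.5)  # edge s->m only
        out = collapse(poly, net, "s", "t")
        # absent s->m disconnects; present s->m alone is not yet a path
        assert out.c == pytest.approx(0.5)
        assert out.b == 0.0
        assert frozenset({0}) in out.terms

    def test_unresolved_term_untouched(self):
        net = fixture("diamond")
        poly = multiply_edge(XYPolynomial.empty(), 0, 0.5)  # one edge of route 1
        out = collapse(poly, net, "s", "t")
        # the other route is unprocessed: neither a path nor a cut yet
        assert out.b == 0.0 and out.c == 0.0
        assert len(out.terms) == 2


class TestReachability:
    def test_single_edge(self):
        assert reachability(fixture("single-edge"), [0.7], "s", "t") == pytest.approx(0.7)

    def test_parallel_routes(self):
        # relay edges pinned at 1: two 0.5 routes in parallel
        assert reachability(fixture("parallel"), [0.5, 0.5, 1, 1], "s", "t") == pytest.approx(0.75)

    def test_diamond(self):
        assert reachability(fixture("diamond"), [0.5] * 4, "s", "t") == pytest.approx(0.4375)

    def test_source_equals_target_is_one(self):
        assert reachability(series_net(), [0.5, 0.5], "m", "m") == 1.0

    def test_unreachable_target_is_zero(self):
        assert reachability(series_net(), [0.5, 0.5], "t", "s") == 0.0

    def test_unknown_node_rejected(self):
        with pytest.raises(ValidationError):
            reachability(series_net(), [0.5, 0.5], "s", "nope")

    def test_cycle_handled_exactly(self):
        net = ProbabilisticNetwork(
            nodes=("s", "a", "b", "t"),
            edges=(("s", "a"), ("a", "b"), ("b", "a"), ("a", "t")),
        )
        p = np.array([0.9, 0.8, 0.7, 0.6])
        assert reachability(net, p, "s", "t") == pytest.approx(
            brute_force_reachability(net, p, "s", "t"), abs=1e-12
        )

    def test_matrix_matches_pairwise_calls(self, rng):
        inst = random_instance(rng, n_sources=2, n_targets=2)
        net = inst.network
        R = reachability_matrix(net, inst.ground_truth)
        for i, s in enumerate(net.sources):
            for j, t in enumerate(net.targets):
                assert R.values[i, j] == pytest.approx(
                    reachability(net, inst.ground_truth, s, t), abs=1e-12
                )

    def test_deterministic_graph_is_indicator(self, rng):
        inst = random_instance(rng)
        net = inst.network
        ones = reachability_matrix(net, np.ones(net.n_edges))
        zeros = reachability_matrix(net, np.zeros(net.n_edges))
        assert set(np.unique(ones.values)) <= {0.0, 1.0}
        assert np.all(zeros.values == 0.0)

    def test_matrix_requires_terminals(self):
        net = ProbabilisticNetwork(nodes=("a", "b"), edges=(("a", "b"),))
        with pytest.raises(ValidationError):
            reachability_matrix(net, [0.5])


class TestOracleEquivalence:
    def test_engine_agrees_with_brute_force_on_100_random_networks(self):
        rng = np.random.default_rng(7)
        for k in range(100):
            inst = random_instance(
                rng,
                n_nodes=int(rng.integers(6, 9)),
                n_edges=int(rng.integers(4, 11)),
                n_sources=1,
                n_targets=1,
            )
            net = inst.network
            p = rng.random(net.n_edges)
            s, t = net.sources[0], net.targets[0]
            assert reachability(net, p, s, t) == pytest.approx(
                brute_force_reachability(net, p, s, t), abs=1e-12
            )

    def test_brute_force_trivial_cases(self):
        assert brute_force_reachability(fixture("single-edge"), [0.7], "s", "t") == pytest.approx(0.7)
        assert brute_force_reachability(series_net(), [0.5, 0.5], "s", "t") == pytest.approx(0.25)

    def test_brute_force_refuses_large_networks(self, rng):
        inst = random_instance(rng, n_nodes=12, n_edges=25, n_sources=1, n_targets=1)
        with pytest.raises(EngineError, match="refused"):
            brute_force_reachability(
                inst.network, inst.ground_truth, inst.network.sources[0], inst.network.targets[0]
            )


class TestConservation:
    def test_mass_conserved_after_every_step(self, rng):
        """b + c + sum(a_i) stays 1 through every multiply/collapse step."""
        for _ in range(20):
            inst = random_instance(rng, n_nodes=7, n_edges=9, n_sources=1, n_targets=1)
            net = inst.network
            s, t = net.sources[0], net.targets[0]
            p = rng.random(net.n_edges)
            poly = XYPolynomial.empty()
            for i in rng.permutation(net.n_edges):
                poly = multiply_edge(poly, int(i), float(p[i]))
                assert poly.total() == pytest.approx(1.0, abs=1e-9)
                poly = collapse(poly, net, s, t)
                assert poly.total() == pytest.approx(1.0, abs=1e-9)
            assert not poly.terms
            assert poly.b == pytest.approx(brute_force_reachability(net, p, s, t), abs=1e-12)

    def test_order_independence_of_final_reached_mass(self, rng):
        """The collapsed polynomial's b is the same for any edge order."""
        for _ in range(10):
            inst = random_instance(rng, n_nodes=7, n_edges=9, n_sources=1, n_targets=1)
            net = inst.network
            s, t = net.sources[0], net.targets[0]
            p = rng.random(net.n_edges)
            results = []
            for _ in range(3):
                poly = XYPolynomial.empty()
                for i in rng.permutation(net.n_edges):
                    poly = collapse(multiply_edge(poly, int(i), float(p[i])), net, s, t)
                results.append(poly.b)
            assert max(results) - min(results) < 1e-12


class TestLinearization:
    def test_single_edge_defer(self):
        lin = linear_coefficients(fixture("single-edge"), [0.3], 0, "s", "t")
        assert (lin.alpha, lin.beta) == (0.0, 1.0)

    def test_parallel_defer(self):
        # defer edge 0 (s->a); other route contributes alpha = 0.5
        lin = linear_coefficients(fixture("parallel"), [0.2, 0.5, 1.0, 1.0], 0, "s", "t")
        assert lin.alpha == pytest.approx(0.5)
        assert lin.beta == pytest.approx(0.5)

    def test_series_defer(self):
        lin = linear_coefficients(series_net(), [0.9, 0.5], 0, "s", "t")
        assert lin.alpha == pytest.approx(0.0)
        assert lin.beta == pytest.approx(0.5)

    def test_irrelevant_edge_has_zero_beta(self):
        net = ProbabilisticNetwork(
            nodes=("s", "t", "x", "y"),
            edges=(("s", "t"), ("x", "y")),
        )
        lin = linear_coefficients(net, [0.7, 0.4], 1, "s", "t")
        assert lin.alpha == pytest.approx(0.7)
        assert lin.beta == 0.0

    def test_endpoints_match_full_evaluations(self):
        """alpha == R(p_e=0) and alpha + beta == R(p_e=1) on random instances."""
        rng = np.random.default_rng(21)
        for _ in range(50):
            inst = random_instance(rng, n_nodes=7, n_edges=8, n_sources=2, n_targets=2)
            net = inst.network
            p = rng.random(net.n_edges)
            e = int(rng.integers(net.n_edges))
            s = net.sources[int(rng.integers(len(net.sources)))]
            t = net.targets[int(rng.integers(len(net.targets)))]
            lin = linear_coefficients(net, p, e, s, t)
            for pe in (0.0, 0.25, 0.5, 0.75, 1.0):
                q = p.copy()
                q[e] = pe
                assert lin(pe) == pytest.approx(reachability(net, q, s, t), abs=1e-9)

    def test_surviving_terms_need_the_deferred_edge(self, rng):
        """Each uncollapsed term has no s->t path without e but one with e."""
        from sigreach.engine import _PairContext

        for _ in range(10):
            inst = random_instance(rng, n_nodes=7, n_edges=9, n_sources=1, n_targets=1)
            net = inst.network
            s, t = net.sources[0], net.targets[0]
            p = rng.random(net.n_edges)
            eng = ReachabilityEngine(net)
            ctx, order = eng._pair(s, t)
            if not order:
                continue
            e = order[-1]
            poly = eng._run(p, s, t, skip_edge=e)
            probe = _PairContext(net, s, t)
            for subset in poly.terms:
                assert not probe.has_path(subset)
                assert probe.has_path(subset | {e})


class TestMonotonicity:
    def test_raising_one_probability_never_lowers_reachability(self, rng):
        for _ in range(10):
            inst = random_instance(rng, n_nodes=7, n_edges=9, n_sources=1, n_targets=1)
            net = inst.network
            s, t = net.sources[0], net.targets[0]
            p = rng.random(net.n_edges)
            base = reachability(net, p, s, t)
            e = int(rng.integers(net.n_edges))
            q = p.copy()
            q[e] = min(1.0, p[e] + rng.random() * (1 - p[e]))
            assert reachability(net, q, s, t) >= base - 1e-12
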