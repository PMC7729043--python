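"""Microstate container, topology generators and stress evaluation."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, strategies as st

from heidersim import (
    ModelParams,
    SignedOpinionNetwork,
    TopologySpec,
    build_regular_ring,
    build_small_world,
    delta_stress_link_flip,
    delta_stress_opinion_flip,
    ground_state_stress,
    randomize_state,
    total_stress,
)

from conftest import make_net, oracle_min_stress, oracle_stress, random_net


class TestTopologies:
    def test_ring_k2_is_cycle(self):
        net = build_regular_ring(TopologySpec(10, 2))
        assert net.n_links == 10
        assert all(net.degree(i) == 2 for i in range(10))

    def test_ring_k4_neighbourhood(self):
        net = build_regular_ring(TopologySpec(10, 4))
        assert net.n_links == 20
        assert set(net.neighbors(0)) == {1, 2, 8, 9}

    @pytest.mark.parametrize("n,k", [(4, 3), (10, 0), (6, 6)])
    def test_bad_degree_rejected(self, n, k):
        with pytest.raises(ValueError):
            TopologySpec(n, k)

    def test_small_world_eps0_is_ring(self):
        ring = build_regular_ring(TopologySpec(20, 4))
        sw = build_small_world(TopologySpec(20, 4, epsilon=0.0, seed=1))
        assert set((a, b) for a, b, _ in ring.links()) == set(
            (a, b) for a, b, _ in sw.links()
        )

    def test_small_world_full_rewiring_connected_and_conserving(self):
        net = build_small_world(TopologySpec(100, 8, epsilon=1.0, seed=3))
        assert net.n_links == 400  # N*k/2 conserved
        g = nx.Graph([(a, b) for a, b, _ in net.links()])
        g.add_nodes_from(range(100))
        assert nx.is_connected(g)
        degrees = [net.degree(i) for i in range(100)]
        assert len(set(degrees)) > 1  # no longer regular
        net.validate()

    def test_small_world_deterministic_under_seed(self):
        a = build_small_world(TopologySpec(50, 6, epsilon=0.4, seed=9))
        b = build_small_world(TopologySpec(50, 6, epsilon=0.4, seed=9))
        assert list(a.links()) == list(b.links())


class TestRandomizeState:
    def test_degenerate_probabilities(self):
        net = build_regular_ring(TopologySpec(12, 4))
        randomize_state(net, p_plus=1.0, p_up=1.0, seed=0)
        assert all(s == 1 for _, _, s in net.links())
        assert np.all(net.opinions == 1)

    def test_sign_fraction_near_half(self):
        net = build_regular_ring(TopologySpec(400, 8), )
        randomize_state(net, seed=5)
        frac = sum(1 for _, _, s in net.links() if s > 0) / net.n_links
        assert abs(frac - 0.5) < 3 * 0.5 / np.sqrt(net.n_links)

    def test_deterministic_under_seed(self):
        net1 = randomize_state(build_regular_ring(TopologySpec(30, 4)), seed=7)
        net2 = randomize_state(build_regular_ring(TopologySpec(30, 4)), seed=7)
        assert np.array_equal(net1.opinions, net2.opinions)
        assert list(net1.links()) == list(net2.links())


class TestStress:
    def test_k4_all_positive(self, k4_all_positive, params_g1):
        assert total_stress(k4_all_positive, params_g1) == -10

    def test_three_cycle(self, params_g1):
        net = make_net(3, [(0, 1, 1), (1, 2, 1), (0, 2, 1)])
        assert total_stress(net, params_g1) == -4  # 3 edges + 1 balanced triangle

    def test_h_term_vanishes_when_all_positive(self, k4_all_positive):
        assert total_stress(k4_all_positive, ModelParams(g=1, T=1, h=0.5)) == -10

    def test_h_term_counts_negative_links(self):
        net = make_net(3, [(0, 1, -1), (1, 2, 1)], opinions=[1, 1, 1])
        # edge term: +1 - 1 = 0; no triangles; h/2 * (1 - (-1)) = h
        assert total_stress(net, ModelParams(g=1, T=1, h=2.0)) == 2.0

    def test_matches_oracle_on_random_nets(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            net = random_net(rng, int(rng.integers(3, 9)))
            for g, h in [(1.0, 0.0), (2.0, 0.0), (0.5, 1.5)]:
                assert total_stress(net, ModelParams(g=g, T=1, h=h)) == pytest.approx(
                    oracle_stress(net, g, h)
                )

    def test_global_opinion_flip_symmetry(self):
        rng = np.random.default_rng(1)
        net = random_net(rng, 8)
        p = ModelParams(g=1.3, T=1, h=0.4)
        H0 = total_stress(net, p)
        net.opinions = (-net.opinions).astype(np.int8)
        assert total_stress(net, p) == pytest.approx(H0)


class TestGroundState:
    def test_k4(self, k4_all_positive, params_g1):
        assert ground_state_stress(k4_all_positive, params_g1) == -10

    def test_triangle_free_ring(self, params_g1):
        net = build_regular_ring(TopologySpec(10, 2))
        assert ground_state_stress(net, params_g1) == -10

    def test_ring_k4(self, params_g1):
        net = build_regular_ring(TopologySpec(10, 4))
        assert ground_state_stress(net, params_g1) == -30  # 20 edges, 10 triangles

    def test_exhaustive_minimum_all_connected_topologies_n_le_4(self):
        # every connected graph on up to 4 labelled nodes
        for n in (2, 3, 4):
            all_pairs = list(itertools.combinations(range(n), 2))
            for r in range(n - 1, len(all_pairs) + 1):
                for edges in itertools.combinations(all_pairs, r):
                    g = nx.Graph(edges)
                    if g.number_of_nodes() < n or not nx.is_connected(g):
                        continue
                    net = make_net(n, [(a, b, 1) for a, b in edges])
                    for gg, hh in [(1.0, 0.0), (2.0, 0.0), (1.0, 0.7)]:
                        expected = oracle_min_stress(list(edges), n, gg, hh)
                        got = ground_state_stress(net, ModelParams(g=gg, T=1, h=hh))
                        assert got == pytest.approx(expected)

    def test_exhaustive_minimum_spot_check_n5(self):
        rng = np.random.default_rng(0)
        for _ in range(3):
            while True:
                net = random_net(rng, 5, p_edge=0.6)
                g = nx.Graph([(a, b) for a, b, _ in net.links()])
                g.add_nodes_from(range(5))
                if nx.is_connected(g):
                    break
            edges = [(a, b) for a, b, _ in net.links()]
            assert ground_state_stress(net, ModelParams(g=1, T=1)) == pytest.approx(
                oracle_min_stress(edges, 5, 1.0, 0.0)
            )

    def test_lower_bounds_random_states(self):
        rng = np.random.default_rng(3)
        p = ModelParams(g=1, T=1)
        for _ in range(200):
            net = random_net(rng, int(rng.integers(4, 12)))
            assert total_stress(net, p) >= ground_state_stress(net, p) - 1e-12


class TestIncrementalDeltas:
    def test_opinion_flip_two_agents(self, params_g1):
        net = make_net(2, [(0, 1, 1)], opinions=[1, 1])
        assert delta_stress_opinion_flip(net, params_g1, 0) == 2

    def test_opinion_flip_isolated_agent(self, params_g1):
        net = make_net(3, [(0, 1, 1)])
        assert delta_stress_opinion_flip(net, params_g1, 2) == 0

    def test_opinion_flip_k4(self, k4_all_positive, params_g1):
        assert delta_stress_opinion_flip(k4_all_positive, params_g1, 1) == 6

    def test_opinion_flip_bad_index(self, k4_all_positive, params_g1):
        with pytest.raises(IndexError):
            delta_stress_opinion_flip(k4_all_positive, params_g1, 7)

    def test_link_flip_three_cycle(self, params_g1):
        net = make_net(3, [(0, 1, 1), (1, 2, 1), (0, 2, 1)], opinions=[1, 1, 1])
        assert delta_stress_link_flip(net, params_g1, 0, 1) == 4

    def test_link_flip_no_common_neighbours(self, params_g1):
        net = make_net(4, [(0, 1, 1), (1, 2, 1), (2, 3, 1)], opinions=[1, 1, 1, 1])
        assert delta_stress_link_flip(net, params_g1, 0, 1) == 2

    def test_link_flip_h_term(self):
        net = make_net(4, [(0, 1, 1), (1, 2, 1), (2, 3, 1)], opinions=[1, 1, 1, 1])
        assert delta_stress_link_flip(net, ModelParams(g=1, T=1, h=2.0), 0, 1) == 4

    def test_link_flip_unlinked_pair(self, params_g1):
        net = make_net(3, [(0, 1, 1)])
        with pytest.raises(KeyError):
            delta_stress_link_flip(net, params_g1, 0, 2)

    @given(st.integers(0, 10_000))
    def test_deltas_match_full_recomputation(self, case):
        """Incremental ΔH must equal total_stress(after) - total_stress(before)
        exactly, for both opinion and link flips."""
        rng = np.random.default_rng(case)
        net = random_net(rng, int(rng.integers(3, 10)))
        p = ModelParams(g=float(rng.integers(0, 3)), T=1.0, h=float(rng.integers(0, 3)))
        H0 = total_stress(net, p)
        i = int(rng.integers(net.n_agents))
        d = delta_stress_opinion_flip(net, p, i)
        net.opinions[i] = -net.opinions[i]
        assert total_stress(net, p) - H0 == pytest.approx(d)
        net.opinions[i] = -net.opinions[i]
        if net.n_links:
            a, b = net.link_at(int(rng.integers(net.n_links)))
            d = delta_stress_link_flip(net, p, a, b)
            net.flip_link(a, b)
            assert total_stress(net, p) - H0 == pytest.approx(d)


class TestContainerAndIO:
    def test_invariants_enforced(self):
        net = SignedOpinionNetwork(4)
        with pytest.raises(ValueError):
            net.add_link(1, 1, 1)
        with pytest.raises(ValueError):
            net.add_link(0, 1, 2)
        net.add_link(0, 1, -1)
        with pytest.raises(ValueError):
            net.add_link(1, 0, 1)  # already linked (symmetry)
        assert net.link_sign(1, 0) == -1
        net.validate()

    def test_remove_link_swap_delete(self):
        net = make_net(4, [(0, 1, 1), (1, 2, -1), (2, 3, 1)])
        assert net.remove_link(1, 2) == -1
        assert net.n_links == 2
        assert not net.has_link(1, 2)
        net.validate()

    def test_edgelist_roundtrip(self, tmp_path):
        rng = np.random.default_rng(11)
        net = random_net(rng, 7)
        e, o = tmp_path / "e.csv", tmp_path / "o.csv"
        net.to_edgelist_csv(e)
        net.to_opinions_csv(o)
        back = SignedOpinionNetwork.from_edgelist_csv(e, o, n_agents=7)
        assert np.array_equal(back.opinions, net.opinions)
        assert sorted(back.links()) == sorted(net.links())

    def test_graphml_export(self, tmp_path):
        net = make_net(3, [(0, 1, -1), (1, 2, 1)], opinions=[1, -1, 1])
        path = tmp_path / "net.graphml"
        net.to_graphml(path)
        g = nx.read_graphml(path)
        assert int(g.edges[("0", "1")]["sign"]) == -1
        assert int(g.nodes["1"]["opinion"]) == -1
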