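"""Graph model construction rules and the shared topological metrics."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import netclust as nc
from conftest import k_complete
from helpers import (
    brute_density,
    brute_in_out,
    brute_maximal_cliques,
    random_network,
)


class TestNetworkConstruction:
    def test_rejects_self_loop(self):
        with pytest.raises(ValueError, match="self-loop"):
            nc.Network([("a", "a")])

    def test_rejects_duplicate_edge(self):
        with pytest.raises(ValueError, match="duplicate"):
            nc.Network([("a", "b"), ("b", "a")])

    def test_rejects_non_positive_weight(self):
        with pytest.raises(ValueError, match="non-positive"):
            nc.Network([("a", "b", 0.0)])

    def test_uncertain_rejects_probability_above_one(self):
        with pytest.raises(ValueError, match="probability"):
            nc.UncertainNetwork([("a", "b", 1.5)])
        net = nc.UncertainNetwork([("a", "b", 1.0), ("b", "c", 0.3)])
        assert net.weight("b", "c") == pytest.approx(0.3)

    def test_isolated_nodes_are_kept(self):
        net = nc.Network([("a", "b")], nodes=["a", "b", "z"])
        assert net.nodes == {"a", "b", "z"}
        assert net.degree("z") == 0


class TestDensity:
    def test_complete_triangle_is_one(self, triangle):
        assert nc.density(triangle, {"a", "b", "c"}) == 1.0

    def test_path_two_thirds(self):
        net = nc.Network([("a", "b"), ("b", "c")])
        assert nc.density(net, {"a", "b", "c"}) == pytest.approx(2 / 3)

    def test_singleton_is_zero(self, triangle):
        assert nc.density(triangle, {"a"}) == 0.0

    def test_unknown_node_raises(self, triangle):
        with pytest.raises(ValueError, match="unknown node"):
            nc.density(triangle, {"a", "zz"})

    def test_matches_brute_count_on_random_graphs(self, rng):
        for _ in range(25):
            net = random_network(rng, 8, 0.4)
            nodes = sorted(net.nodes)
            k = int(rng.integers(1, 9))
            members = set(rng.choice(nodes, size=k, replace=False))
            assert nc.density(net, members) == pytest.approx(brute_density(net, members))


class TestCommonNeighbors:
    def test_triangle_edge_sees_third_vertex(self, triangle):
        assert nc.common_neighbors(triangle, "a", "b") == {"c"}

    def test_disjoint_components_share_nothing(self):
        net = nc.Network([("a", "b"), ("x", "y")])
        assert nc.common_neighbors(net, "a", "x") == set()

    def test_matches_adjacency_intersection(self, rng):
        for _ in range(25):
            net = random_network(rng, 10, 0.35)
            nodes = sorted(net.nodes)
            u, v = (str(x) for x in rng.choice(nodes, size=2, replace=False))
            adj_u = {b if a == u else a for a, b, _ in net.edges() if u in (a, b)}
            adj_v = {b if a == v else a for a, b, _ in net.edges() if v in (a, b)}
            assert nc.common_neighbors(net, u, v) == (adj_u & adj_v) - {u, v}


class TestInOutDegree:
    def test_isolated_clique_member(self):
        net = k_complete("abcd")
        assert nc.in_out_degree(net, "a", set("abcd")) == (3.0, 0.0)

    def test_pendant_with_external_neighbor(self):
        net = nc.Network([("p", "q")])
        assert nc.in_out_degree(net, "p", {"p"}) == (0.0, 1.0)

    def test_vertex_outside_members_raises(self, triangle):
        with pytest.raises(ValueError, match="not in the member set"):
            nc.in_out_degree(triangle, "a", {"b", "c"})

    def test_matches_edge_scan_on_random_weighted_graphs(self, rng):
        for _ in range(25):
            net = random_network(rng, 9, 0.4, weighted=True)
            nodes = sorted(net.nodes)
            k = int(rng.integers(1, 10))
            members = set(str(x) for x in rng.choice(nodes, size=k, replace=False))
            v = sorted(members)[0]
            got = nc.in_out_degree(net, v, members)
            want = brute_in_out(net, v, members)
            assert got == pytest.approx(want)

    def test_internal_sum_is_twice_internal_weight(self, rng):
        net = random_network(rng, 10, 0.4, weighted=True)
        members = set(sorted(net.nodes)[:6])
        total_in = sum(nc.in_out_degree(net, v, members)[0] for v in members)
        internal = sum(w for a, b, w in net.edges() if a in members and b in members)
        assert total_in == pytest.approx(2 * internal)


class TestInducedDiameter:
    def test_any_clique_has_diameter_one(self):
        assert nc.induced_diameter_at_most(k_complete("abcde"), set("abcde"), 1)

    def test_path_of_four_exceeds_two(self):
        net = nc.Network([("a", "b"), ("b", "c"), ("c", "d")])
        assert not nc.induced_diameter_at_most(net, set("abcd"), 2)
        assert nc.induced_diameter_at_most(net, set("abcd"), 3)

    def test_disconnected_members_fail(self):
        net = nc.Network([("a", "b"), ("x", "y")])
        assert not nc.induced_diameter_at_most(net, {"a", "x"}, 5)

    def test_matches_all_pairs_bfs(self, rng):
        import networkx as nx

        for _ in range(20):
            net = random_network(rng, 10, 0.25)
            nodes = sorted(net.nodes)
            k = int(rng.integers(2, 8))
            members = set(str(x) for x in rng.choice(nodes, size=k, replace=False))
            d = int(rng.integers(1, 4))
            sub = net.graph.subgraph(members)
            if nx.is_connected(sub):
                want = max(
                    dist
                    for lengths in dict(nx.all_pairs_shortest_path_length(sub)).values()
                    for dist in lengths.values()
                ) <= d
            else:
                want = False
            assert nc.induced_diameter_at_most(net, members, d) == want


class TestMaximalCliques:
    def test_k4_is_one_clique(self):
        assert nc.maximal_cliques(k_complete("abcd"), 2) == [frozenset("abcd")]

    def test_five_cycle_has_no_triangle(self):
        cyc = nc.Network([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("e", "a")])
        assert nc.maximal_cliques(cyc, 3) == []

    def test_matches_subset_enumeration(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 13))
            net = random_network(rng, n, float(rng.uniform(0.2, 0.6)))
            for min_size in (2, 3):
                assert nc.maximal_cliques(net, min_size) == brute_maximal_cliques(
                    net, min_size
                )

    def test_results_are_cliques_and_antichain(self, rng):
        net = random_network(rng, 12, 0.4)
        cliques = nc.maximal_cliques(net, 3)
        for c in cliques:
            assert all(net.has_edge(u, v) for u, v in itertools.combinations(sorted(c), 2))
        for a, b in itertools.combinations(cliques, 2):
            assert not a < b and not b < a


class TestOverlapScores:
    @pytest.mark.parametrize(
        "a,b,omega,omin",
        [
            (set("abc"), set("abc"), 1.0, 1.0),
            (set("abc"), set("xyz"), 0.0, 0.0),
            (set("abcd"), set("ab"), 4 / 8, 1.0),
            (set("ab"), set("abcde"), 4 / 10, 1.0),
            (set("ab"), set("bcdef"), 1 / 10, 0.5),
        ],
    )
    def test_known_values(self, a, b, omega, omin):
        assert nc.overlap_omega(a, b) == pytest.approx(omega)
        assert nc.overlap_min(a, b) == pytest.approx(omin)

    def test_empty_set_raises(self):
        with pytest.raises(ValueError):
            nc.overlap_omega(set(), {"a"})
        with pytest.raises(ValueError):
            nc.overlap_min({"a"}, set())

    @given(
        st.sets(st.integers(0, 15), min_size=1).map(lambda s: {str(x) for x in s}),
        st.sets(st.integers(0, 15), min_size=1).map(lambda s: {str(x) for x in s}),
    )
    def test_symmetry_and_range(self, a, b):
        for fn in (nc.overlap_omega, nc.overlap_min):
            x = fn(a, b)
            assert x == pytest.approx(fn(b, a))
            assert 0.0 <= x <= 1.0


class TestClusterMetrics:
    def test_isolated_triangle(self, triangle):
        assert nc.cluster_metrics(triangle, set("abc")) == (1.0, 3.0, 1.0)

    def test_single_node_with_external_edge(self):
        net = nc.Network([("a", "b")])
        assert nc.cluster_metrics(net, {"a"}) == (0.0, 0.0, 0.0)

    def test_matches_edge_classification(self, rng):
        for _ in range(25):
            net = random_network(rng, 10, 0.35)
            nodes = sorted(net.nodes)
            k = int(rng.integers(1, 11))
            members = set(str(x) for x in rng.choice(nodes, size=k, replace=False))
            e_in = sum(1 for a, b, _ in net.edges() if a in members and b in members)
            e_out = sum(1 for a, b, _ in net.edges() if (a in members) != (b in members))
            dens, score, modularity = nc.cluster_metrics(net, members)
            assert dens == pytest.approx(brute_density(net, members))
            assert score == pytest.approx(dens * len(members))
            want_mod = e_in / (e_in + e_out) if e_in + e_out else 0.0
            assert modularity == pytest.approx(want_mod)
            assert 0.0 <= dens <= 1.0 and 0.0 <= modularity <= 1.0 and score >= 0.0

    def test_cluster_from_members_caches_consistent_values(self, rng):
        net = random_network(rng, 8, 0.5)
        members = set(sorted(net.nodes)[:5])
        c = nc.Cluster.from_members(net, members)
        assert (c.density, c.score, c.modularity) == nc.cluster_metrics(net, members)
        assert c.size == len(c.members) == 5
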