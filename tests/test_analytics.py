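import math
import random

import networkx as nx
import pytest

from colnet.cwn_model import Team, build_cwn
from colnet.network_analytics import (
    average_degree,
    average_degree_by_part,
    betweenness,
    connected_components,
    density,
    detect_communities,
    island_filter,
    team_size_stats,
)
from colnet.scn_model import build_scn
from colnet.synthetic_data import ground_truth_eval
from conftest import make_record
from oracles import brute_betweenness, union_find_components


def random_graph(rng, n, p):
    g = nx.Graph()
    g.add_nodes_from(f"n{i}" for i in range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(f"n{i}", f"n{j}")
    return g


class TestComponents:
    def test_edgeless_graph_gives_singletons(self):
        g = nx.Graph()
        g.add_nodes_from("abc")
        comp = connected_components(g)
        assert comp.sizes() == [1, 1, 1]
        # deterministic tie-break: lexicographic smallest member
        assert [min(c) for c in comp.components] == ["a", "b", "c"]

    def test_path_plus_isolate(self):
        g = nx.Graph([("a", "b"), ("b", "c")])
        g.add_node("d")
        comp = connected_components(g)
        assert comp.components == [frozenset("abc"), frozenset("d")]
        assert comp.giant == frozenset("abc")

    def test_matches_union_find_oracle(self):
        rng = random.Random(5)
        for _ in range(20):
            g = random_graph(rng, 30, 0.05)
            comp = connected_components(g)
            assert set(comp.components) == union_find_components(g.nodes, g.edges)
            assert comp.sizes() == sorted(comp.sizes(), reverse=True)

    def test_bipartite_part_counts(self, five_record_fixture):
        scn = build_scn(five_record_fixture)
        comp = connected_components(scn)
        assert comp.part_counts is not None
        total = {"collector": 0, "taxon": 0}
        for counts in comp.part_counts:
            for part, c in counts.items():
                total[part] += c
        assert total == {"collector": scn.n_collectors, "taxon": scn.n_taxa}


class TestDensity:
    def test_complete_bipartite_2x3_is_one(self):
        recs = [
            make_record(f"r{i}{j}", [f"c{i},x"], f"T{j}") for i in range(2) for j in range(3)
        ]
        assert density(build_scn(recs)) == 1.0

    def test_triangle_is_one(self):
        assert density(nx.complete_graph(3)) == 1.0

    def test_fixture_counts(self, five_record_fixture):
        scn = build_scn(five_record_fixture)
        assert density(scn) == scn.n_edges / (scn.n_collectors * scn.n_taxa)

    def test_giant_component_scope_excludes_isolates(self):
        g = nx.Graph([("a", "b"), ("b", "c")])
        g.add_nodes_from(["d", "e"])
        assert density(g, "whole") == 2 * 2 / (5 * 4)
        assert density(g, "giant_component") == 2 * 2 / (3 * 2)
        assert density(g, "whole") <= density(g, "giant_component")

    def test_degenerate_inputs_signalled(self):
        with pytest.raises(ValueError):
            density(nx.Graph())
        g = nx.Graph()
        g.add_node("a")
        with pytest.raises(ValueError):
            density(g)
        with pytest.raises(ValueError):
            density(g, scope="partial")


class TestAverageDegree:
    def test_star_and_edgeless(self):
        assert average_degree(nx.star_graph(4)) == pytest.approx(1.6)
        g = nx.Graph()
        g.add_nodes_from("ab")
        assert average_degree(g) == 0.0

    def test_matches_degree_sum(self):
        rng = random.Random(13)
        g = random_graph(rng, 25, 0.2)
        assert average_degree(g) == pytest.approx(sum(d for _, d in g.degree) / 25)

    def test_per_part_averages(self, five_record_fixture):
        scn = build_scn(five_record_fixture)
        per_part = average_degree_by_part(scn)
        assert per_part["collector"] == pytest.approx(scn.n_edges / scn.n_collectors)
        assert per_part["taxon"] == pytest.approx(scn.n_edges / scn.n_taxa)


class TestBetweenness:
    def test_path_midpoint_is_one(self):
        g = nx.Graph([("a", "b"), ("b", "c")])
        bc = betweenness(g)
        assert bc["b"] == pytest.approx(1.0)
        assert bc["a"] == bc["c"] == 0.0

    def test_star_leaves_are_zero(self):
        bc = betweenness(nx.star_graph(5))
        assert all(bc[leaf] == 0.0 for leaf in range(1, 6))
        assert bc[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("normalized", [True, False])
    def test_matches_exhaustive_path_enumeration(self, normalized):
        rng = random.Random(23)
        for _ in range(8):
            g = random_graph(rng, 12, 0.3)
            got = betweenness(g, normalized=normalized)
            expected = brute_betweenness(g.nodes, g.edges, normalized=normalized)
            for node in g.nodes:
                assert got[node] == pytest.approx(expected[node], abs=1e-12)

    def test_weights_ignored_for_path_length(self):
        # heavy direct edge must not reroute shortest paths
        g = nx.Graph()
        g.add_edge("a", "b", weight=100.0)
        g.add_edge("b", "c", weight=100.0)
        g.add_edge("a", "c", weight=0.001)
        assert betweenness(g)["b"] == 0.0


class TestCommunities:
    def test_disjoint_triangles_split(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c")])
        g.add_edges_from([("x", "y"), ("y", "z"), ("x", "z")])
        part = detect_communities(g, seed=0)
        assert part.n_communities == 2
        assert part.assignment["a"] == part.assignment["b"] == part.assignment["c"]
        assert part.assignment["x"] == part.assignment["y"] == part.assignment["z"]
        assert part.assignment["a"] != part.assignment["x"]

    def test_planted_two_block_recovered(self):
        rng = random.Random(99)
        g = nx.Graph()
        labels = {}
        for block, names in enumerate((range(20), range(20, 40))):
            for i in names:
                g.add_node(f"n{i}")
                labels[f"n{i}"] = block
        nodes = sorted(g.nodes)
        for i, u in enumerate(nodes):
            for v in nodes[i + 1 :]:
                p = 0.9 if labels[u] == labels[v] else 0.02
                if rng.random() < p:
                    g.add_edge(u, v)
        part = detect_communities(g, seed=7)
        assert ground_truth_eval(part.assignment, labels) == 1.0

    def test_modularity_bounds_and_nonnegative_vs_trivial(self):
        rng = random.Random(1)
        g = random_graph(rng, 30, 0.1)
        g.remove_nodes_from(list(nx.isolates(g)))
        part = detect_communities(g, seed=0)
        assert -1.0 <= part.modularity <= 1.0
        assert part.modularity >= 0.0  # trivial one-community partition scores 0

    def test_fixed_seed_reproducible(self):
        rng = random.Random(2)
        g = random_graph(rng, 40, 0.1)
        a = detect_communities(g, seed=5)
        b = detect_communities(g, seed=5)
        assert a.assignment == b.assignment
        assert a.modularity == b.modularity


class TestTeamStats:
    def test_small_examples(self):
        teams = [Team("r0", ("a,x",)), Team("r1", ("b,y",)), Team("r2", ("a,x", "b,y"))]
        stats = team_size_stats(teams)
        assert stats.histogram == {1: 2, 2: 1}
        assert stats.mean == pytest.approx(4 / 3)

    def test_uniform_sizes(self):
        teams = [Team(f"r{i}", (f"a{i},x", f"b{i},y")) for i in range(5)]
        assert team_size_stats(teams).mean == 2.0

    def test_empty_signalled(self):
        with pytest.raises(ValueError):
            team_size_stats([])


class TestIslandFilter:
    @pytest.fixture
    def cwn(self):
        teams = []
        # pair (a,b) shares 12 records; pair (c,d) shares 5 -> weights 12 and 5
        teams += [Team(f"p{i}", ("a,x", "b,y")) for i in range(12)]
        teams += [Team(f"q{i}", ("c,z", "d,w")) for i in range(5)]
        return build_cwn(teams, scheme="hyperbolic")

    def test_zero_thresholds_are_identity(self, cwn):
        g, islands = island_filter(cwn, 0, 0, lambda n: 1)
        assert g.number_of_edges() == cwn.n_edges
        assert sum(len(i) for i, _ in islands) == cwn.n_collectors

    def test_edge_threshold_ten_keeps_one_edge(self, cwn):
        g, islands = island_filter(cwn, 10, 0, lambda n: 1)
        assert list(g.edges) == [("a,x", "b,y")]

    def test_island_scores_and_min_score(self, cwn):
        counts = {"a,x": 12, "b,y": 12, "c,z": 5, "d,w": 5}
        g, islands = island_filter(cwn, 0, 20, counts.get)
        assert {frozenset(i) for i, _ in islands} == {frozenset({"a,x", "b,y"})}
        assert all(score >= 20 for _, score in islands)
        assert set(g.nodes) == {"a,x", "b,y"}
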