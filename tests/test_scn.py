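import random

import numpy as np
import pytest

from colnet.errors import ColnetError, RecordRejectedError
from colnet.scn_model import (
    aggregate,
    build_scn,
    filter_scn_edges,
    quorum,
    species_bag,
)
from conftest import make_record, random_records
from oracles import tally_scn


class TestBuildScn:
    def test_one_record_two_collectors_makes_two_unit_edges(self):
        scn = build_scn([make_record("r0", ["a,x", "b,y"], "Myrtia alba")])
        assert scn.weight("a,x", "Myrtia alba") == 1
        assert scn.weight("b,y", "Myrtia alba") == 1
        assert scn.n_edges == 2

    def test_repeated_association_strengthens_edge(self):
        recs = [make_record(f"r{i}", ["a,x"], "Myrtia alba") for i in range(3)]
        scn = build_scn(recs)
        assert scn.n_edges == 1
        assert scn.weight("a,x", "Myrtia alba") == 3

    def test_empty_input_gives_empty_network(self):
        scn = build_scn([])
        assert scn.biadjacency().shape == (0, 0)
        assert scn.n_collectors == scn.n_taxa == scn.n_edges == 0

    def test_precondition_violations_rejected_with_ids(self):
        bad = [make_record("r0", [], "X"), make_record("r1", ["a,x"], "")]
        with pytest.raises(RecordRejectedError) as exc:
            build_scn(bad)
        assert set(exc.value.record_ids) == {"r0", "r1"}

    def test_bipartite_with_no_within_part_edges(self, five_record_fixture):
        scn = build_scn(five_record_fixture)
        parts = {n: d["part"] for n, d in scn.graph.nodes(data=True)}
        assert all(parts[u] != parts[v] for u, v in scn.graph.edges)

    def test_biadjacency_matches_brute_force_tally(self):
        rng = random.Random(42)
        for _ in range(20):
            records = random_records(rng, n_records=rng.randint(1, 50))
            scn = build_scn(records)
            expected = tally_scn(records)
            A = scn.biadjacency().toarray()
            got = {
                (c, t): int(A[i, j])
                for i, c in enumerate(scn.collectors)
                for j, t in enumerate(scn.taxa)
                if A[i, j]
            }
            assert got == dict(expected)


class TestBagAndQuorum:
    def test_single_edge_bag(self):
        scn = build_scn([make_record("r0", ["a,x"], "Myrtia alba")])
        bag = species_bag(scn, "a,x")
        assert bag.nonzero() == {"Myrtia alba": 1}

    def test_bag_sum_equals_record_count(self, five_record_fixture):
        scn = build_scn(five_record_fixture)
        for cid in scn.collectors:
            n_records = sum(1 for r in five_record_fixture if cid in r.collector_ids)
            assert species_bag(scn, cid).total() == n_records

    def test_quorum_is_transpose_of_bags(self, five_record_fixture):
        scn = build_scn(five_record_fixture)
        for j, taxon in enumerate(scn.taxa):
            q = quorum(scn, taxon)
            for i, cid in enumerate(scn.collectors):
                assert q.counts[i] == species_bag(scn, cid).counts[j]

    def test_five_record_fixture_against_tally(self, five_record_fixture):
        scn = build_scn(five_record_fixture)
        expected = tally_scn(five_record_fixture)
        bag = species_bag(scn, "a,x")
        assert bag.nonzero() == {"Myrtia alba": 2, "Myrtia nitida": 1}
        for (cid, taxon), count in expected.items():
            assert species_bag(scn, cid).nonzero()[taxon] == count

    def test_unknown_nodes_raise(self, five_record_fixture):
        scn = build_scn(five_record_fixture)
        with pytest.raises(KeyError):
            species_bag(scn, "nobody,x")
        with pytest.raises(KeyError):
            quorum(scn, "Nullia species")


class TestAggregate:
    def test_two_species_one_family_sums_weights(self):
        recs = [make_record(f"r{i}", ["a,x"], "Myrtia alba") for i in range(2)]
        recs += [make_record(f"s{i}", ["a,x"], "Myrtia nitida") for i in range(3)]
        scn = build_scn(recs)
        fam = aggregate(scn, {"Myrtia alba": "Myrtaceae", "Myrtia nitida": "Myrtaceae"}, "family")
        assert fam.weight("a,x", "Myrtaceae") == 5
        assert fam.resolution == "family"

    def test_identity_grouping_is_isomorphic(self, five_record_fixture):
        scn = build_scn(five_record_fixture)
        out = aggregate(scn, {t: t for t in scn.taxa}, "species")
        assert out.collectors == scn.collectors and out.taxa == scn.taxa
        assert (out.biadjacency() != scn.biadjacency()).nnz == 0

    def test_conservation_of_total_and_row_sums(self):
        rng = random.Random(7)
        for _ in range(10):
            records = random_records(rng, n_records=rng.randint(5, 40))
            scn = build_scn(records)
            taxonomy = {t: f"fam{sum(map(ord, t)) % 3}" for t in scn.taxa}
            agg = aggregate(scn, taxonomy, "family")
            assert agg.total_weight() == scn.total_weight()
            before = scn.biadjacency().sum(axis=1)
            after = agg.biadjacency().sum(axis=1)
            assert np.array_equal(np.asarray(before), np.asarray(after))
            assert agg.collectors == scn.collectors

    def test_missing_species_listed_as_orphans(self, five_record_fixture):
        scn = build_scn(five_record_fixture)
        with pytest.raises(ColnetError, match="Fabia minor"):
            aggregate(scn, {"Myrtia alba": "Myrtaceae", "Myrtia nitida": "Myrtaceae"}, "family")


class TestFilterEdges:
    @pytest.fixture
    def weighted_scn(self):
        recs = []
        for count, (cid, taxon) in zip(
            [1, 19, 20, 25],
            [("a,x", "T1"), ("a,x", "T2"), ("b,y", "T1"), ("b,y", "T3")],
        ):
            recs += [make_record(f"{cid}-{taxon}-{i}", [cid], taxon) for i in range(count)]
        return build_scn(recs)

    def test_min_weight_one_is_identity(self, weighted_scn):
        out = filter_scn_edges(weighted_scn, 1)
        assert out.n_edges == weighted_scn.n_edges

    def test_threshold_twenty_keeps_two_edges(self, weighted_scn):
        out = filter_scn_edges(weighted_scn, 20)
        assert out.n_edges == 2
        assert sorted(d["weight"] for _, _, d in out.graph.edges(data=True)) == [20, 25]

    def test_isolate_drop_leaves_no_degree_zero(self, weighted_scn):
        out = filter_scn_edges(weighted_scn, 20, drop_isolates=True)
        assert all(out.graph.degree(n) > 0 for n in out.graph.nodes)
        assert set(out.collectors) | set(out.taxa) == set(out.graph.nodes)

    def test_min_weight_below_one_rejected(self, weighted_scn):
        with pytest.raises(ValueError):
            filter_scn_edges(weighted_scn, 0)
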