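"""Clustering semantics: threshold graph, greedy set cover, reassignment."""

import random

import pytest

from scsh import cluster as clu
from scsh.types import AlignmentRecord, Clustering, PhageMetadata, SimilarityGraph


def aln(q, t, ident, qcov, tcov):
    return AlignmentRecord(q, t, ident, qcov, tcov, 1e-10)


def graph_from_edges(nodes, edges):
    g = SimilarityGraph()
    for n in nodes:
        g.add_node(n)
    for a, b in edges:
        g.add_edge(a, b)
    return g


def assert_partition(clustering, node_ids):
    members = [m for ms in clustering.clusters.values() for m in ms]
    assert len(members) == len(set(members)), "overlapping clusters"
    assert set(members) == set(node_ids), "not exhaustive"
    for rep, ms in clustering.clusters.items():
        assert rep in ms


class TestSimilarityGraph:
    def test_edge_at_default_thresholds(self):
        g = clu.build_similarity_graph([aln("q", "t", 0.6, 0.95, 0.92)])
        assert g.has_edge("q", "t")

    def test_bidirectional_coverage_failure_drops_edge(self):
        g = clu.build_similarity_graph([aln("q", "t", 0.6, 0.95, 0.85)])
        assert not g.has_edge("q", "t")
        assert {"q", "t"} <= g.node_ids  # nodes still registered

    def test_thresholds_inclusive_at_boundary(self):
        g = clu.build_similarity_graph([aln("q", "t", 0.5, 0.9, 0.9)])
        assert g.has_edge("q", "t")

    def test_target_mode_ignores_query_coverage(self):
        g = clu.build_similarity_graph(
            [aln("q", "t", 0.6, 0.5, 0.95)], coverage_mode="target"
        )
        assert g.has_edge("q", "t")

    def test_raising_identity_never_adds_edges(self):
        rng = random.Random(5)
        records = [
            aln(f"n{rng.randrange(10)}", f"n{rng.randrange(10)}",
                rng.random(), rng.random(), rng.random())
            for _ in range(200)
        ]
        records = [r for r in records if r.query_id != r.target_id]
        prev = None
        for ident in (0.2, 0.4, 0.6, 0.8):
            edges = clu.build_similarity_graph(records, min_identity=ident,
                                               min_coverage=0.3).edges
            if prev is not None:
                assert edges <= prev
            prev = edges


class TestGreedySetCover:
    def test_edgeless_graph_gives_singletons(self):
        g = graph_from_edges("abcde", [])
        c = clu.greedy_set_cover_cluster(g)
        assert len(c) == 5
        assert all(len(m) == 1 for m in c.clusters.values())

    def test_star_collapses_to_hub(self):
        g = graph_from_edges("abcd", [("a", "b"), ("a", "c"), ("a", "d")])
        c = clu.greedy_set_cover_cluster(g)
        assert c.clusters == {"a": {"a", "b", "c", "d"}}

    def test_path_center_covers_all(self):
        g = graph_from_edges("abc", [("a", "b"), ("b", "c")])
        c = clu.greedy_set_cover_cluster(g)
        assert c.clusters == {"b": {"a", "b", "c"}}

    def test_partition_and_determinism_on_random_graphs(self):
        rng = random.Random(17)
        for _ in range(50):
            n = rng.randrange(2, 9)
            nodes = [f"n{i}" for i in range(n)]
            edges = [
                (a, b)
                for i, a in enumerate(nodes)
                for b in nodes[i + 1:]
                if rng.random() < 0.4
            ]
            g = graph_from_edges(nodes, edges)
            c1 = clu.greedy_set_cover_cluster(g)
            c2 = clu.greedy_set_cover_cluster(graph_from_edges(nodes, edges))
            assert_partition(c1, nodes)
            assert c1 == c2

    def test_cluster_count_nondecreasing_as_edges_removed(self):
        rng = random.Random(23)
        nodes = [f"n{i}" for i in range(8)]
        edges = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]
                 if rng.random() < 0.5]
        while True:
            g = graph_from_edges(nodes, edges)
            before = len(clu.greedy_set_cover_cluster(g))
            if not edges:
                break
            edges = edges[:-1]
            after = len(clu.greedy_set_cover_cluster(graph_from_edges(nodes, edges)))
            assert after >= before


class TestReassign:
    def test_member_moves_to_connected_rep(self):
        g = graph_from_edges(["r", "r2", "m"], [("m", "r2")])
        c = Clustering({"r": {"r", "m"}, "r2": {"r2"}})
        out = clu.reassign_members(c, g)
        assert out.clusters == {"r": {"r"}, "r2": {"r2", "m"}}

    def test_disconnected_member_becomes_singleton(self):
        g = graph_from_edges(["r", "m"], [])
        c = Clustering({"r": {"r", "m"}})
        out = clu.reassign_members(c, g)
        assert out.clusters == {"r": {"r"}, "m": {"m"}}

    def test_fixed_point_when_all_members_touch_reps(self):
        g = graph_from_edges("rab", [("r", "a"), ("r", "b")])
        c = Clustering({"r": {"r", "a", "b"}})
        assert clu.reassign_members(c, g) == c

    def test_smallest_qualifying_rep_wins(self):
        g = graph_from_edges(["a", "z", "r", "m"], [("m", "a"), ("m", "z")])
        c = Clustering({"r": {"r", "m"}, "a": {"a"}, "z": {"z"}})
        out = clu.reassign_members(c, g)
        assert "m" in out.clusters["a"]

    def test_idempotent_on_random_fixtures(self):
        rng = random.Random(31)
        for _ in range(30):
            n = rng.randrange(3, 10)
            nodes = [f"n{i}" for i in range(n)]
            full_edges = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]
                          if rng.random() < 0.5]
            g_full = graph_from_edges(nodes, full_edges)
            c = clu.greedy_set_cover_cluster(g_full)
            reduced = [e for e in full_edges if rng.random() < 0.6]
            g_red = graph_from_edges(nodes, reduced)
            once = clu.reassign_members(c, g_red)
            twice = clu.reassign_members(once, g_red)
            assert once == twice
            assert_partition(once, nodes)


class TestSizeSummary:
    def test_counts_singletons_and_pairs(self):
        c = Clustering({"a": {"a"}, "b": {"b"}, "c": {"c"}, "d": {"d", "e"}})
        table = dict(clu.cluster_size_summary(c))
        assert table["1"] == 3 and table["2"] == 1

    def test_empty_clustering_all_zero(self):
        table = dict(clu.cluster_size_summary(Clustering({})))
        assert all(v == 0 for v in table.values())

    def test_counts_sum_to_cluster_count(self, bundle):
        table = clu.cluster_size_summary(bundle.planted_clustering)
        assert sum(v for _k, v in table) == len(bundle.planted_clustering)


class TestMixedLifestyleScreen:
    META = [
        PhageMetadata("ph1", "A", "temperate"),
        PhageMetadata("ph2", "B", "lytic"),
        PhageMetadata("ph3", "A", "lytic"),
    ]

    def test_mixed_cluster_selected(self):
        c = Clustering({"r": {"r", "m"}})
        sel = clu.screen_mixed_lifestyle_clusters(
            c, {"r": "ph1", "m": "ph2"}, self.META
        )
        assert sel == {"r"}

    def test_single_lifestyle_cluster_not_selected(self):
        c = Clustering({"r": {"r", "m"}})
        sel = clu.screen_mixed_lifestyle_clusters(
            c, {"r": "ph2", "m": "ph3"}, self.META
        )
        assert sel == set()

    def test_singletons_excluded(self):
        c = Clustering({"r": {"r"}})
        sel = clu.screen_mixed_lifestyle_clusters(c, {"r": "ph1"}, self.META)
        assert sel == set()

    def test_unmapped_protein_is_error(self):
        c = Clustering({"r": {"r", "m"}})
        with pytest.raises(ValueError, match="m"):
            clu.screen_mixed_lifestyle_clusters(c, {"r": "ph1"}, self.META)
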