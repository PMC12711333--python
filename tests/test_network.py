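"""IBD network construction, filters, communities, and topology metrics."""

import numpy as np
import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from ibdnet.metadata import IndividualRecord
from ibdnet.pedigree import IBDSegment, drop_haplotypes, pairwise_ibd, simulate_pedigree
from ibdnet.network import (
    PairIBDSummary,
    build_graph,
    detect_communities,
    export_graph,
    flag_relative_pairs,
    import_graph,
    largest_component,
    module_metrics,
    node_metrics,
    summarize_pairs,
)


def seg(a, b, length, ch="1", start=0.0):
    return IBDSegment(a, b, ch, start, start + length)


def rec(iid, lo=900, hi=1000, group="G"):
    return IndividualRecord(iid, lo, hi, group)


class TestSummarizePairs:
    def test_threshold_arithmetic(self):
        s = summarize_pairs([seg("x", "y", 15), seg("x", "y", 13), seg("x", "y", 5)])
        (p,) = s
        assert p.n_ge[12.0] == 2
        assert p.max_cm == pytest.approx(15)
        assert p.sum_gt12_cm == pytest.approx(28)
        assert p.n_ge[8.0] == 2 and p.n_ge[9.0] == 2

    def test_strong_pair_sums_like_top_published_pairs(self):
        # four long segments summing to 144 cM of > 12 cM sharing
        s = summarize_pairs(
            [seg("x", "y", l) for l in (50, 40, 30, 24)]
        )
        assert s[0].sum_gt12_cm == pytest.approx(144)
        assert s[0].n_ge[12.0] == 4

    def test_empty_input(self):
        assert summarize_pairs([]) == []

    def test_non_positive_lengths_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            summarize_pairs([seg("x", "y", 0.0)])

    @settings(max_examples=50, deadline=None)
    @given(
        lengths=st.lists(
            st.floats(min_value=0.1, max_value=200, allow_nan=False), min_size=1, max_size=20
        )
    )
    def test_counts_non_increasing_in_threshold(self, lengths):
        (p,) = summarize_pairs([seg("x", "y", l) for l in lengths])
        assert p.n_ge[8.0] >= p.n_ge[9.0] >= p.n_ge[12.0]
        assert p.max_cm >= max(lengths) - 1e-9
        assert p.sum_gt12_cm >= 0


# hand-enumerated fixture: the post-filter edge set is derived by hand.
#   dates: all 900-1000 CE (midpoint 950) except F at 100-200 CE (gap 800 y)
#   segments: A-B 20, B-C 13, C-D 12, D-A 9.0 (boundary: kept),
#             D-E 15 (E ends with degree 1 -> dropped),
#             A-F 30 (temporal filter removes), E-F 8.5 (below 9: no edge)
#   expected: nodes {A,B,C,D}, edges {AB, BC, CD, DA}
FIXTURE_SEGMENTS = [
    seg("A", "B", 20.0), seg("B", "C", 13.0), seg("C", "D", 12.0),
    seg("D", "A", 9.0), seg("D", "E", 15.0), seg("A", "F", 30.0),
    seg("E", "F", 8.5),
]
FIXTURE_META = [rec(i) for i in "ABCDE"] + [rec("F", 100, 200)]


class TestBuildGraph:
    def test_hand_enumerated_fixture(self):
        g = build_graph(summarize_pairs(FIXTURE_SEGMENTS), FIXTURE_META)
        assert set(g.nodes) == {"A", "B", "C", "D"}
        assert {tuple(sorted(e)) for e in g.edges} == {
            ("A", "B"), ("B", "C"), ("C", "D"), ("A", "D")
        }
        assert g.edges["A", "B"]["weight"] == pytest.approx(20.0)
        counts = g.graph["filter_counts"]
        assert counts["edges_after_segment_filter"] == 6
        assert counts["edges_after_temporal_filter"] == 5
        assert counts["nodes_after_degree_filter"] == 4

    def test_segment_below_nine_cm_makes_no_edge(self):
        pairs = summarize_pairs([seg("A", "B", 8.5)])
        g = build_graph(pairs, [rec("A"), rec("B")], min_degree=0)
        assert g.number_of_edges() == 0

    def test_temporal_gap_over_600_years_removes_edge(self):
        pairs = summarize_pairs([seg("A", "B", 20.0)])
        meta = [rec("A", 900, 1000), rec("B", 100, 200)]  # midpoints 950 vs 150
        g = build_graph(pairs, meta, min_degree=0)
        assert g.number_of_edges() == 0
        # interval-gap mode measures interval distance instead
        g2 = build_graph(pairs, meta, min_degree=0, temporal_mode="gap",
                        max_year_gap=700.0)
        assert g2.number_of_edges() == 1

    def test_unknown_individual_named_in_error(self):
        pairs = summarize_pairs([seg("A", "ghost", 20.0)])
        with pytest.raises(ValueError, match="ghost"):
            build_graph(pairs, [rec("A")])

    def test_filter_pipeline_idempotent(self):
        g = build_graph(summarize_pairs(FIXTURE_SEGMENTS), FIXTURE_META)
        pairs2 = [
            PairIBDSummary(
                pair=tuple(sorted((a, b))),
                n_ge={8.0: 1, 9.0: 1, 12.0: d["n_ge12"]},
                max_cm=d["max_cm"],
                sum_gt12_cm=d["sum_gt12_cm"],
            )
            for a, b, d in g.edges(data=True)
        ]
        meta2 = [m for m in FIXTURE_META if m.id in g.nodes]
        g2 = build_graph(pairs2, meta2)
        assert nx.utils.graphs_equal(
            nx.Graph(g.edges(data=True)), nx.Graph(g2.edges(data=True))
        )

    def test_threshold_monotonicity_on_random_inputs(self):
        """Raising min_edge_cM never adds edges; raising max_year_gap never
        removes them (checked end-to-end, degree filter included)."""
        for s in range(100):
            rng = np.random.default_rng(s)
            ids = [f"n{i}" for i in range(25)]
            years = rng.integers(0, 1200, size=len(ids))
            meta = [rec(i, lo=int(y), hi=int(y) + 100) for i, y in zip(ids, years)]
            segs = []
            for _ in range(60):
                a, b = rng.choice(len(ids), size=2, replace=False)
                segs.append(seg(ids[a], ids[b], float(rng.uniform(5, 20)),
                                start=float(rng.uniform(0, 50))))
            pairs = summarize_pairs(segs)
            loose = build_graph(pairs, meta, min_edge_cm=9, max_year_gap=600)
            strict = build_graph(pairs, meta, min_edge_cm=11, max_year_gap=600)
            wide = build_graph(pairs, meta, min_edge_cm=9, max_year_gap=900)
            assert set(map(frozenset, strict.edges)) <= set(map(frozenset, loose.edges))
            assert set(map(frozenset, loose.edges)) <= set(map(frozenset, wide.edges))


class TestLargestComponent:
    def test_returns_biggest_component(self):
        g = nx.Graph()
        nx.add_path(g, [f"a{i}" for i in range(10)])
        nx.add_path(g, ["z1", "z2", "z3"])
        assert set(largest_component(g).nodes) == {f"a{i}" for i in range(10)}

    def test_connected_graph_unchanged(self):
        g = nx.path_graph(5)
        assert nx.utils.graphs_equal(largest_component(g), g)

    def test_tie_breaks_to_smallest_node_id(self):
        g = nx.Graph()
        nx.add_path(g, ["m1", "m2", "m3", "m4"])
        nx.add_path(g, ["a1", "a2", "a3", "a4"])
        assert set(largest_component(g).nodes) == {"a1", "a2", "a3", "a4"}

    def test_empty_graph(self):
        assert largest_component(nx.Graph()).number_of_nodes() == 0


class TestDetectCommunities:
    def make_two_cliques(self):
        g = nx.Graph()
        for base in ("L", "R"):
            for i in range(10):
                for j in range(i + 1, 10):
                    g.add_edge(f"{base}{i}", f"{base}{j}", weight=10.0)
        g.add_edge("L0", "R0", weight=10.0)
        return g

    def test_two_cliques_split_at_bridge(self):
        part = detect_communities(self.make_two_cliques(), seed=0)
        coms = part.communities
        assert len(coms) == 2
        sides = [set(v) for v in coms.values()]
        assert {frozenset(s) for s in sides} == {
            frozenset(f"L{i}" for i in range(10)),
            frozenset(f"R{i}" for i in range(10)),
        }
        assert part.quality > 0.3

    def test_triangle_is_one_community(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c")], weight=5.0)
        part = detect_communities(g, seed=1)
        assert len(part.communities) == 1

    def test_deterministic_given_seed(self):
        g = self.make_two_cliques()
        p1 = detect_communities(g, seed=3)
        p2 = detect_communities(g, seed=3)
        assert p1.membership == p2.membership

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            detect_communities(nx.Graph())


class TestNodeMetrics:
    def test_degree_split(self):
        g = nx.star_graph(5)  # center 0 with 5 leaves
        member = {0: "A", 1: "A", 2: "A", 3: "A", 4: "B", 5: "B"}
        df = node_metrics(g, member).set_index("id")
        assert df.loc[0, "k"] == 5
        assert df.loc[0, "kW"] == 3
        assert df.loc[0, "kB"] == 2

    def test_kw_plus_kb_equals_k_everywhere(self):
        rng = np.random.default_rng(0)
        g = nx.gnp_random_graph(40, 0.15, seed=1)
        member = {n: int(rng.integers(4)) for n in g.nodes}
        df = node_metrics(g, member)
        assert (df["kW"] + df["kB"] == df["k"]).all()

    def test_clustering_coefficient_cases(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"), ("c", "d"), ("d", "e")])
        member = {n: 0 for n in g.nodes}
        df = node_metrics(g, member).set_index("id")
        assert df.loc["a", "cc"] == pytest.approx(1.0)  # triangle node
        assert df.loc["d", "cc"] == pytest.approx(0.0)  # degree-2, open
        assert ((df["cc"] >= 0) & (df["cc"] <= 1)).all()

    def test_missing_node_rejected(self):
        g = nx.path_graph(3)
        with pytest.raises(ValueError, match="missing from partition"):
            node_metrics(g, {0: 0, 1: 0})


class TestModuleMetrics:
    def test_within_strength_and_average(self):
        g = nx.Graph()
        g.add_edge("a", "b", sum_gt12_cm=30.0)
        g.add_edge("b", "c", sum_gt12_cm=50.0)
        df = module_metrics(g, {"a": "M", "b": "M", "c": "M"}).set_index("module")
        assert df.loc["M", "within_strength"] == pytest.approx(80)
        assert df.loc["M", "avg_ibd_within"] == pytest.approx(40)
        assert df.loc["M", "between_strength"] == 0
        assert np.isnan(df.loc["M", "avg_ibd_between"])

    def test_between_strength_attributed_to_both_modules(self):
        g = nx.Graph()
        g.add_edge("a", "b", sum_gt12_cm=24.0)
        df = module_metrics(g, {"a": "X", "b": "Y"}).set_index("module")
        assert df.loc["X", "between_strength"] == pytest.approx(24)
        assert df.loc["Y", "between_strength"] == pytest.approx(24)

    def test_strength_conservation(self):
        rng = np.random.default_rng(2)
        g = nx.gnp_random_graph(30, 0.2, seed=3)
        for a, b in g.edges:
            g.edges[a, b]["sum_gt12_cm"] = float(rng.uniform(12, 60))
        member = {n: int(rng.integers(3)) for n in g.nodes}
        df = module_metrics(g, member)
        intra = sum(d["sum_gt12_cm"] for a, b, d in g.edges(data=True)
                    if member[a] == member[b])
        inter = sum(d["sum_gt12_cm"] for a, b, d in g.edges(data=True)
                    if member[a] != member[b])
        assert df["within_strength"].sum() == pytest.approx(intra)
        assert df["between_strength"].sum() == pytest.approx(2 * inter)


class TestFlagRelatives:
    def test_three_long_segments_flagged(self):
        pairs = summarize_pairs([seg("x", "y", l) for l in (20, 15, 13)])
        assert len(flag_relative_pairs(pairs)) == 1

    def test_two_segments_need_laxer_rule(self):
        pairs = summarize_pairs([seg("x", "y", l) for l in (20, 15)])
        assert len(flag_relative_pairs(pairs)) == 0
        assert len(flag_relative_pairs(pairs, min_segments=2)) == 1

    def test_simulated_parent_child_is_first_degree(self, gmap, nuclear):
        ped, haps = nuclear
        segs = pairwise_ibd(haps, min_cm=8.0)
        flagged = flag_relative_pairs(summarize_pairs(segs))
        parent = ped.founders[0]
        child = [i for i in ped.members if ped.parents[i]][0]
        key = tuple(sorted((parent, child)))
        row = flagged[(flagged["iid1"] == key[0]) & (flagged["iid2"] == key[1])]
        assert len(row) == 1
        assert row["degree_class"].iloc[0] == "1st"


class TestExportImport:
    def test_round_trip_graph_equality(self, tmp_path):
        g = build_graph(summarize_pairs(FIXTURE_SEGMENTS), FIXTURE_META)
        part = detect_communities(g, seed=0)
        paths = export_graph(g, part, tmp_path)
        back = import_graph(paths["nodes"], paths["edges"])
        assert set(back.nodes) == set(g.nodes)
        assert set(map(frozenset, back.edges)) == set(map(frozenset, g.edges))
        for a, b in g.edges:
            assert back.edges[a, b]["max_cm"] == pytest.approx(g.edges[a, b]["max_cm"])
            assert back.edges[a, b]["sum_gt12_cm"] == pytest.approx(
                g.edges[a, b]["sum_gt12_cm"]
            )
        # community ids present on every node record
        assert all("community" in back.nodes[n] for n in back.nodes)

    def test_gexf_parses_and_is_deterministic(self, tmp_path):
        g = build_graph(summarize_pairs(FIXTURE_SEGMENTS), FIXTURE_META)
        part = detect_communities(g, seed=0)
        p1 = export_graph(g, part, tmp_path / "a")["gexf"]
        p2 = export_graph(g, part, tmp_path / "b")["gexf"]
        assert p1.read_bytes() == p2.read_bytes()
        parsed = nx.read_gexf(p1)
        assert set(parsed.nodes) == set(g.nodes)

    def test_empty_graph_exports_valid_gexf(self, tmp_path):
        paths = export_graph(nx.Graph(), None, tmp_path)
        parsed = nx.read_gexf(paths["gexf"])
        assert parsed.number_of_nodes() == 0
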