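"""Target intersection, network construction, centralities and hub screens.

Betweenness is checked against an exhaustive shortest-path enumeration
oracle (predecessor-DAG walk over Floyd-Warshall distances) written
independently of the Brandes implementation, and against networkx as a
second opinion.
"""
import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from phytonet import (ParseError, TargetMapping, ValidationError,
                      apply_centrality_thresholds, build_network,
                      centralities, ct_degree_rank, gen_ppi_network,
                      gen_target_sets, hub_screen, intersect_targets,
                      tier1_screen, tier2_screen)
from phytonet.datasets import PUBLISHED_TIER2_THRESHOLDS
from phytonet.netpharm import BipartiteCT


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def _floyd_warshall(g):
    nodes = sorted(g.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for u, v in g.edges:
        dist[idx[u], idx[v]] = dist[idx[v], idx[u]] = 1.0
    for k in range(n):
        dist = np.minimum(dist, dist[:, [k]] + dist[[k], :])
    return nodes, idx, dist


def _all_shortest_paths(g, idx, dist, s, t):
    """Every shortest s-t path, by walking the predecessor DAG backwards."""
    if not np.isfinite(dist[idx[s], idx[t]]):
        return []
    paths = []

    def walk(v, suffix):
        if v == s:
            paths.append([s] + suffix)
            return
        for u in g.neighbors(v):
            if dist[idx[s], idx[u]] == dist[idx[s], idx[v]] - 1:
                walk(u, [v] + suffix)

    walk(t, [])
    return paths


def brute_force_centralities(g):
    nodes, idx, dist = _floyd_warshall(g)
    n = len(nodes)
    bc = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        paths = _all_shortest_paths(g, idx, dist, s, t)
        for path in paths:
            for v in path[1:-1]:
                bc[v] += 1.0 / len(paths)
    cc = {}
    for v in nodes:
        d = dist[idx[v]]
        finite = d[np.isfinite(d)]
        reach = finite.size - 1
        total = finite.sum()
        cc[v] = (reach / total) * (reach / (n - 1)) if total > 0 else 0.0
    dc = {v: g.degree(v) for v in nodes}
    return dc, bc, cc


# ---------------------------------------------------------------------------
# intersection
# ---------------------------------------------------------------------------

class TestIntersect:
    def test_hand_counts(self):
        m = TargetMapping({"c1": {"A", "B"}, "c2": {"B", "C"}},
                          {"B", "C", "D"})
        venn = intersect_targets(m)
        assert (venn.compound_union, venn.disease, venn.overlap) == (3, 3, 2)
        assert venn.overlap_genes == {"B", "C"}

    def test_disease_equals_universe(self):
        m = TargetMapping({"c": {"a", "b"}}, {"A", "B", "C"})
        venn = intersect_targets(m)
        assert venn.overlap_genes == {"A", "B"}  # symbols uppercased

    def test_planted_core_guarantees_overlap(self):
        universe = [f"G{i:04d}" for i in range(1, 2001)]
        ts = gen_target_sets(19, universe, 50, 80, 0.9, seed=11)
        m = TargetMapping(ts.compound_targets, ts.disease_genes)
        assert intersect_targets(m).overlap >= 50

    def test_empty_sets_rejected(self):
        with pytest.raises(ValidationError):
            intersect_targets(TargetMapping({"c": set()}, {"A"}))


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

class TestBuildNetwork:
    def test_strict_threshold_semantics(self):
        edges = [("a", "b", 0.39), ("b", "c", 0.40), ("c", "d", 0.41)]
        net = build_network(edges, min_confidence=0.4)
        assert net.number_of_edges() == 1
        assert net.has_edge("c", "d")
        lenient = build_network(edges, min_confidence=0.4, strict=False)
        assert lenient.number_of_edges() == 2

    def test_string_dialect_autodetected(self):
        net = build_network([("a", "b", 700), ("b", "c", 250)])
        assert net["a"]["b"]["confidence"] == pytest.approx(0.700)
        assert not net.has_edge("b", "c")  # 0.25 below the 0.4 threshold

    def test_isolated_node_removed(self):
        edges = [("hub", f"leaf{i}", 0.9) for i in range(3)]
        net = build_network(edges, nodes=["hub", "leaf0", "leaf1", "leaf2",
                                          "alone"])
        assert net.number_of_nodes() == 4
        assert net.number_of_edges() == 3

    def test_malformed_row_reports_line(self):
        with pytest.raises(ParseError):
            build_network([("a", "b")])

    def test_out_of_range_confidence_rejected(self):
        with pytest.raises(ParseError):
            build_network([("a", "b", 1200), ("c", "d", -5)])

    def test_largest_component_option(self):
        edges = [("a", "b", 0.9), ("b", "c", 0.9), ("x", "y", 0.9)]
        net = build_network(edges, largest_component=True)
        assert sorted(net.nodes) == ["a", "b", "c"]


# ---------------------------------------------------------------------------
# centralities
# ---------------------------------------------------------------------------

class TestCentralities:
    def test_path_graph_hand_values(self):
        g = nx.path_graph(["a", "b", "c"])
        t = centralities(g)
        assert t.loc["b", "dc"] == 2
        assert t.loc["b", "bc"] == pytest.approx(1.0)
        assert t.loc["b", "cc"] == pytest.approx(1.0)
        assert t.loc["a", "cc"] == pytest.approx(2 / 3)

    def test_star_graph_hand_values(self):
        g = nx.star_graph(3)  # center 0 among 4 nodes
        t = centralities(g)
        assert t.loc[0, "dc"] == 3
        assert t.loc[0, "bc"] == pytest.approx(3.0)
        assert t.loc[0, "cc"] == pytest.approx(1.0)
        for leaf in (1, 2, 3):
            assert t.loc[leaf, "cc"] == pytest.approx(0.6)
            assert t.loc[leaf, "bc"] == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_exhaustive_oracle_on_small_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        p = float(rng.uniform(0.2, 0.7))
        g = nx.gnp_random_graph(n, p, seed=seed)
        if g.number_of_edges() == 0:
            g.add_edge(0, 1)
        t = centralities(g)
        dc, bc, cc = brute_force_centralities(g)
        for v in g.nodes:
            assert t.loc[v, "dc"] == dc[v]
            assert t.loc[v, "bc"] == pytest.approx(bc[v], abs=1e-9)
            assert t.loc[v, "cc"] == pytest.approx(cc[v], abs=1e-9)

    def test_matches_networkx_conventions(self):
        g = nx.gnp_random_graph(30, 0.15, seed=7)
        t = centralities(g)
        nx_bc = nx.betweenness_centrality(g, normalized=False)
        nx_cc = nx.closeness_centrality(g)
        for v in g.nodes:
            assert t.loc[v, "bc"] == pytest.approx(nx_bc[v], abs=1e-8)
            assert t.loc[v, "cc"] == pytest.approx(nx_cc[v], abs=1e-9)

    def test_structural_invariants(self):
        g = gen_ppi_network(120, 3, seed=2)
        t = centralities(g)
        assert t.dc.sum() == 2 * g.number_of_edges()
        leaves = t.index[t.dc == 1]
        assert (t.loc[leaves, "bc"] == 0).all()
        assert ((t.cc >= 0) & (t.cc <= 1)).all()

    def test_empty_graph_rejected(self):
        with pytest.raises(ValidationError):
            centralities(nx.Graph())


# ---------------------------------------------------------------------------
# hub screens
# ---------------------------------------------------------------------------

def _graph_with_degrees():
    # degrees [1, 1, 2, 2, 10, 12]-like shape: two hubs and satellites
    g = nx.Graph()
    g.add_edges_from([("h1", f"s{i}") for i in range(10)])
    g.add_edges_from([("h2", f"s{i}") for i in range(10, 22)])
    g.add_edge("h1", "h2")
    return g


class TestTierScreens:
    def test_tier1_keeps_nodes_at_twice_median(self):
        g = _graph_with_degrees()
        t1 = tier1_screen(g, multiplier=2.0)
        # satellites have degree 1, hubs 11 and 13; median is 1
        assert set(t1.network.nodes) == {"h1", "h2"}
        assert t1.threshold == pytest.approx(2.0)

    def test_multiplier_zero_is_identity(self):
        g = gen_ppi_network(60, 2, seed=4)
        t1 = tier1_screen(g, multiplier=0.0)
        assert set(t1.network.nodes) == set(g.nodes)

    def test_tier1_nested_in_multiplier(self):
        g = gen_ppi_network(150, 3, seed=9)
        small = set(tier1_screen(g, multiplier=1.0).network.nodes)
        large = set(tier1_screen(g, multiplier=2.0).network.nodes)
        assert large <= small

    def test_all_filtered_warns_and_returns_empty(self):
        g = nx.cycle_graph(6)  # all degrees equal, median 2, threshold 20
        with pytest.warns(UserWarning):
            t1 = tier1_screen(g, multiplier=10.0)
        assert t1.network.number_of_nodes() == 0

    def test_complete_graph_retains_everyone_in_tier2(self):
        g = nx.complete_graph(6)
        res = tier2_screen(g)
        assert len(res.core) == 6  # all at the median, kept by >=

    def test_dominant_node_lands_in_core(self):
        g = nx.star_graph(4)
        g.add_edge(1, 2)
        res = tier2_screen(g)
        assert 0 in res.core.index

    def test_singleton_rejected(self):
        g = nx.Graph()
        g.add_node("x")
        with pytest.raises(ValidationError):
            tier2_screen(g)

    def test_published_hub_rows_survive_their_own_thresholds(self, hub_table):
        kept = apply_centrality_thresholds(hub_table,
                                           **PUBLISHED_TIER2_THRESHOLDS)
        assert len(kept) == 19
        assert list(kept.index[:4]) == ["ESR1", "CASP3", "PPARG", "PTGS2"]

    def test_screens_idempotent(self):
        g = gen_ppi_network(200, 4, seed=6)
        t1 = tier1_screen(g, multiplier=2.0)
        again = tier1_screen(t1.network, multiplier=0.0)
        assert set(again.network.nodes) == set(t1.network.nodes)

    @pytest.mark.parametrize("seed", range(20))
    def test_planted_hub_recovery(self, seed):
        g = gen_ppi_network(300, 3, seed=seed, planted_hubs=5)
        res = hub_screen(g, multiplier=2.0)
        hubs = set(g.graph["planted_hubs"])
        tier1_nodes = set(res.tier1.network.nodes)
        assert hubs <= tier1_nodes
        recall = len(hubs & set(res.core_nodes)) / len(hubs)
        assert recall >= 0.9


# ---------------------------------------------------------------------------
# compound-target bipartite ranking
# ---------------------------------------------------------------------------

class TestDegreeRank:
    def test_published_scores_median_and_core(self, degree_scores):
        rank = ct_degree_rank(degree_scores)
        assert rank.cutoff == 133
        assert len(rank.core) == 10
        assert rank.core[-1] == "1,8-Cineole (Eucalyptol)"

    def test_single_compound_is_the_core(self):
        bip = BipartiteCT({"only": {"T1", "T2"}})
        rank = ct_degree_rank(bip)
        assert rank.core == ["only"]
        assert rank.cutoff == 2

    def test_degree_counts_distinct_targets(self):
        bip = BipartiteCT.from_edges([("c", "T1"), ("c", "T1"), ("c", "T2")])
        assert bip.degrees == {"c": 2}

    @pytest.mark.parametrize("seed", range(10))
    def test_odd_distinct_degrees_give_majority_core(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.choice([5, 7, 9, 11]))
        degrees = rng.choice(np.arange(1, 200), size=n, replace=False)
        rank = ct_degree_rank({f"c{i}": int(d) for i, d in enumerate(degrees)})
        assert len(rank.core) == (n + 1) // 2

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            ct_degree_rank({})
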