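import math
import random
from itertools import combinations

import networkx as nx
import pytest

from pcsf import (
    Forest,
    GeneSetCollection,
    SolverParams,
    assign_prizes,
    cluster_subnetwork,
    construct_interactome,
    enrich,
    make_forest,
    solve_pcsf,
)


def _forest_from_edges(edges, extra_nodes=()):
    nodes = frozenset({v for e in edges for v in e} | set(extra_nodes))
    g = nx.Graph(list(edges))
    g.add_nodes_from(extra_nodes)
    k = nx.number_connected_components(g)
    return Forest(
        nodes=nodes,
        edges=frozenset(tuple(sorted(e)) for e in edges),
        k=k,
        objective=0.0,
        steiner_nodes=frozenset(),
        terminal_nodes=nodes,
    )


def brute_force_edge_betweenness(g: nx.Graph) -> dict:
    """Shortest-path edge betweenness by explicit enumeration of all
    shortest paths between every node pair (independent of networkx's
    accumulation algorithm)."""
    bt = {tuple(sorted(e)): 0.0 for e in g.edges}
    for s, t in combinations(sorted(g.nodes), 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for path in paths:
            for u, v in zip(path, path[1:]):
                bt[tuple(sorted((u, v)))] += 1.0 / len(paths)
    return bt


def hypergeom_tail_brute_force(x, M, K, n):
    """P(overlap >= x) as an explicit sum of hypergeometric point masses."""
    total = 0.0
    for i in range(x, min(K, n) + 1):
        total += math.comb(K, i) * math.comb(M - K, n - i) / math.comb(M, n)
    return total


TRIANGLES_BRIDGE = [
    ("a1", "a2"), ("a2", "a3"), ("a1", "a3"),
    ("b1", "b2"), ("b2", "b3"), ("b1", "b3"),
    ("a3", "b1"),
]


class TestClusterSubnetwork:
    def test_bridge_between_triangles_has_maximal_betweenness(self):
        g = nx.Graph(TRIANGLES_BRIDGE)
        bt = brute_force_edge_betweenness(g)
        assert max(bt, key=bt.get) == ("a3", "b1")

    def test_two_triangles_split_at_the_bridge(self):
        clustering = cluster_subnetwork(_forest_from_edges(TRIANGLES_BRIDGE))
        assert clustering.n_clusters == 2
        members = clustering.members
        assert set(members[1]) == {"a1", "a2", "a3"}
        assert set(members[2]) == {"b1", "b2", "b3"}

    def test_agrees_with_igraph_edge_betweenness_communities(self):
        igraph = pytest.importorskip("igraph")
        nodes = sorted({v for e in TRIANGLES_BRIDGE for v in e})
        idx = {v: i for i, v in enumerate(nodes)}
        ig = igraph.Graph([(idx[u], idx[v]) for u, v in TRIANGLES_BRIDGE])
        ref = ig.community_edge_betweenness().as_clustering()
        ref_parts = {frozenset(nodes[i] for i in c) for c in ref}
        ours = cluster_subnetwork(_forest_from_edges(TRIANGLES_BRIDGE))
        our_parts = {frozenset(vs) for vs in ours.members.values()}
        assert our_parts == ref_parts

    def test_single_triangle_stays_one_cluster(self):
        clustering = cluster_subnetwork(
            _forest_from_edges([("a", "b"), ("b", "c"), ("a", "c")])
        )
        assert clustering.n_clusters == 1

    def test_components_are_never_merged(self):
        f = _forest_from_edges([("a", "b"), ("c", "d")], extra_nodes=["e"])
        clustering = cluster_subnetwork(f)
        assert clustering.n_clusters >= 3
        m = dict(clustering.membership)
        assert m["a"] == m["b"] and m["c"] == m["d"]
        assert len({m["a"], m["c"], m["e"]}) == 3

    def test_cluster_ids_contiguous_from_one(self):
        clustering = cluster_subnetwork(_forest_from_edges(TRIANGLES_BRIDGE))
        ids = {c for _, c in clustering.membership}
        assert ids == set(range(1, clustering.n_clusters + 1))

    def test_empty_subnetwork_rejected(self):
        g = assign_prizes(
            construct_interactome([("A", "B", 0.5)]), {"A": 0.1}, SolverParams(w=2.0)
        )
        empty = make_forest(g, [], [], SolverParams(w=2.0))
        with pytest.raises(ValueError):
            cluster_subnetwork(empty)

    def test_works_on_solver_output(self, toy1):
        g, params = toy1
        clustering = cluster_subnetwork(solve_pcsf(g, params))
        assert clustering.n_clusters >= 1


def _clustering_of(members_by_cluster):
    from pcsf.annotate import Clustering

    membership = tuple(
        sorted((v, c) for c, vs in members_by_cluster.items() for v in vs)
    )
    return Clustering(
        membership=membership, n_clusters=len(members_by_cluster), modularity=0.0
    )


class TestEnrich:
    def test_perfect_overlap_closed_form(self):
        universe = [f"g{i:03d}" for i in range(100)]
        cluster = universe[:10]
        gsc = GeneSetCollection.from_sets({"S": cluster}, universe)
        table = enrich(_clustering_of({1: cluster}), gsc)
        assert table.loc[0, "overlap"] == 10
        assert table.loc[0, "p_raw"] == pytest.approx(1 / math.comb(100, 10), rel=1e-12)

    def test_zero_overlap_gives_p_one(self):
        universe = [f"g{i}" for i in range(50)]
        gsc = GeneSetCollection.from_sets({"S": universe[20:30]}, universe)
        table = enrich(_clustering_of({1: universe[:10]}), gsc)
        assert table.loc[0, "p_raw"] == pytest.approx(1.0)

    def test_2x2_table_matches_brute_force_tail(self):
        # table (3,2,1,14): cluster 5, set 4, universe 20, overlap 3
        universe = [f"g{i}" for i in range(20)]
        cluster = universe[:5]
        sset = universe[:3] + [universe[7]]
        gsc = GeneSetCollection.from_sets({"S": sset}, universe)
        table = enrich(_clustering_of({1: cluster}), gsc)
        assert table.loc[0, "p_raw"] == pytest.approx(
            hypergeom_tail_brute_force(3, 20, 4, 5), rel=1e-12
        )

    def test_random_tables_match_brute_force(self):
        rng = random.Random(2025)
        universe = [f"g{i}" for i in range(30)]
        for _ in range(100):
            n_c = rng.randint(1, 15)
            n_s = rng.randint(1, 15)
            cluster = rng.sample(universe, n_c)
            sset = rng.sample(universe, n_s)
            gsc = GeneSetCollection.from_sets({"S": sset}, universe)
            table = enrich(_clustering_of({1: cluster}), gsc)
            x = len(set(cluster) & set(sset))
            expected = hypergeom_tail_brute_force(x, 30, n_s, n_c)
            assert table.loc[0, "p_raw"] == pytest.approx(expected, rel=1e-12)

    def test_bh_adjustment_is_monotone_and_at_least_raw(self):
        rng = random.Random(7)
        universe = [f"g{i}" for i in range(60)]
        sets = {
            f"S{j}": rng.sample(universe, rng.randint(5, 20)) for j in range(12)
        }
        gsc = GeneSetCollection.from_sets(sets, universe)
        table = enrich(_clustering_of({1: rng.sample(universe, 15)}), gsc, top_k=None)
        assert (table["p_adj"] >= table["p_raw"] - 1e-15).all()
        by_raw = table.sort_values(["p_raw", "set_name"])
        assert by_raw["p_adj"].is_monotonic_increasing

    def test_top_k_and_ranking_stability(self):
        universe = [f"g{i}" for i in range(40)]
        sets = {f"S{j}": universe[5:15] for j in range(20)}  # all identical: tie
        gsc = GeneSetCollection.from_sets(sets, universe)
        table = enrich(_clustering_of({1: universe[:10]}), gsc, top_k=15)
        assert len(table) == 15
        assert list(table["set_name"]) == sorted(table["set_name"])

    def test_overlap_bounds_invariant(self):
        universe = [f"g{i}" for i in range(30)]
        gsc = GeneSetCollection.from_sets({"S": universe[:8]}, universe)
        table = enrich(_clustering_of({1: universe[4:10]}), gsc)
        row = table.iloc[0]
        assert 0 <= row["overlap"] <= min(row["cluster_size"], row["set_size"])

    def test_empty_universe_rejected(self):
        gsc = GeneSetCollection.from_sets({"S": ["a"]}, [])
        with pytest.raises(ValueError):
            enrich(_clustering_of({1: ["a"]}), gsc)

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError):
            GeneSetCollection.from_sets({"S": []}, ["a"])
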