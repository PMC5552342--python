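"""Functional annotation of a solution subnetwork.

Two steps mirror common practice for interpreting extracted subnetworks:

1. **Clustering** by Girvan–Newman edge-betweenness: edges of maximal
   shortest-path betweenness are removed iteratively, and the cut level
   that maximizes modularity over the resulting dendrogram is kept.
   Connectivity is never merged — every connected component is split into
   one or more clusters, and singletons form their own clusters.

2. **Gene-set enrichment** per cluster with the one-sided Fisher exact
   test (the hypergeometric upper tail) against a local GMT gene-set
   collection. The sampling universe is the full template interactome —
   the frame from which the subnetwork was drawn — not the genome.
   P-values are Benjamini–Hochberg adjusted within each cluster across all
   tested sets, and the top-ranking sets per cluster are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Union

import networkx as nx
import pandas as pd
from networkx.algorithms import community as nx_community
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .randomization import RobustForest
from .solver import Forest

__all__ = [
    "Clustering",
    "GeneSetCollection",
    "ENRICHMENT_COLUMNS",
    "cluster_subnetwork",
    "enrich",
]

#: Columns of the enrichment table returned by :func:`enrich`.
ENRICHMENT_COLUMNS = [
    "cluster",
    "set_name",
    "overlap",
    "cluster_size",
    "set_size",
    "universe_size",
    "p_raw",
    "p_adj",
    "overlap_nodes",
]


@dataclass(frozen=True)
class Clustering:
    """A hard partition of the subnetwork nodes into clusters 1..n_clusters."""

    membership: tuple[tuple[str, int], ...]
    n_clusters: int
    modularity: float

    @property
    def members(self) -> dict[int, list[str]]:
        """Cluster id -> sorted member nodes."""
        out: dict[int, list[str]] = {}
        for v, c in self.membership:
            out.setdefault(c, []).append(v)
        return {c: sorted(vs) for c, vs in out.items()}

    def cluster_of(self, v: str) -> int:
        return dict(self.membership)[v]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets with descriptions, plus the enrichment universe.

    Set members need not be a subset of the universe; they are intersected
    with it at test time. Empty sets are rejected.
    """

    sets: tuple[tuple[str, str, frozenset[str]], ...]  # (name, description, members)
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for name, _, members in self.sets:
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
        names = [name for name, _, _ in self.sets]
        if len(names) != len(set(names)):
            raise ValueError("duplicate gene-set names")

    @classmethod
    def from_sets(
        cls,
        sets: Mapping[str, Iterable[str]],
        universe: Iterable[str],
        descriptions: Mapping[str, str] | None = None,
    ) -> "GeneSetCollection":
        descriptions = descriptions or {}
        rows = tuple(
            (name, descriptions.get(name, ""), frozenset(members))
            for name, members in sorted(sets.items())
        )
        return cls(sets=rows, universe=frozenset(universe))


def _as_graph(subnet: Union[Forest, RobustForest]) -> nx.Graph:
    if isinstance(subnet, RobustForest):
        nodes, edges = subnet.union_nodes, subnet.union_edges
    else:
        nodes, edges = subnet.nodes, subnet.edges
    g = nx.Graph()
    g.add_nodes_from(sorted(nodes))
    g.add_edges_from(sorted(edges))
    return g


def cluster_subnetwork(subnet: Union[Forest, RobustForest]) -> Clustering:
    """Cluster a subnetwork by divisive edge-betweenness (Girvan–Newman).

    The dendrogram level with maximal modularity is selected, starting from
    the trivial partition into connected components (so a partition is
    never coarser than connectivity). Cluster ids are contiguous integers
    from 1, assigned in order of each cluster's smallest node id.

    Raises
    ------
    ValueError
        If the subnetwork is empty.
    """
    g = _as_graph(subnet)
    if g.number_of_nodes() == 0:
        raise ValueError("cannot cluster an empty subnetwork")

    components = [frozenset(c) for c in nx.connected_components(g)]
    if g.number_of_edges() == 0:
        best, best_q = components, 0.0
    else:
        best, best_q = components, nx_community.modularity(g, components)
        for level in nx_community.girvan_newman(g):
            q = nx_community.modularity(g, level)
            if q > best_q + 1e-12:
                best, best_q = [frozenset(c) for c in level], q

    clusters = sorted(best, key=lambda c: min(c))
    membership = tuple(
        sorted((v, i) for i, c in enumerate(clusters, start=1) for v in c)
    )
    return Clustering(membership=membership, n_clusters=len(clusters), modularity=best_q)


def enrich(
    clustering: Clustering,
    gsc: GeneSetCollection,
    top_k: int = 15,
) -> pd.DataFrame:
    """Per-cluster gene-set enrichment with the one-sided Fisher exact test.

    For each (cluster, set) pair the 2x2 table over the universe is

        [[in cluster & in set, in cluster & not in set],
         [in set & not in cluster, in neither]]

    and the enrichment p-value is the hypergeometric upper tail
    ``P(overlap >= observed)``. Within each cluster, p-values are
    Benjamini–Hochberg adjusted across all tested sets, rows are ranked by
    (adjusted p, raw p, set name) and the best ``top_k`` are kept.

    Returns a :class:`pandas.DataFrame` with columns
    ``ENRICHMENT_COLUMNS``. Pass ``top_k=None`` to keep all rows.

    Raises
    ------
    ValueError
        If the universe or the clustering is empty.
    """
    if not gsc.universe:
        raise ValueError("empty enrichment universe")
    if not clustering.membership:
        raise ValueError("empty clustering")
    universe = gsc.universe
    M = len(universe)
    filtered_sets = [
        (name, members & universe) for name, _, members in gsc.sets
    ]
    rows = []
    for cid, members in sorted(clustering.members.items()):
        cluster = frozenset(members) & universe
        n = len(cluster)
        cluster_rows = []
        for name, sset in filtered_sets:
            K = len(sset)
            overlap = cluster & sset
            x = len(overlap)
            # P(X >= x) for X ~ Hypergeom(M, K, n)
            p_raw = float(stats.hypergeom.sf(x - 1, M, K, n)) if K else 1.0
            p_raw = min(1.0, p_raw)
            cluster_rows.append(
                {
                    "cluster": cid,
                    "set_name": name,
                    "overlap": x,
                    "cluster_size": n,
                    "set_size": K,
                    "universe_size": M,
                    "p_raw": p_raw,
                    "overlap_nodes": ",".join(sorted(overlap)),
                }
            )
        if not cluster_rows:
            continue
        praw = [r["p_raw"] for r in cluster_rows]
        p_adj = multipletests(praw, method="fdr_bh")[1]
        for r, adj in zip(cluster_rows, p_adj):
            r["p_adj"] = float(adj)
        cluster_rows.sort(key=lambda r: (r["p_adj"], r["p_raw"], r["set_name"]))
        rows.extend(cluster_rows if top_k is None else cluster_rows[:top_k])
    return pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS)
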