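"""Data model for the template interaction network.

The prize-collecting Steiner forest (PCSF) machinery operates on an
undirected *interactome*: a simple graph whose nodes are biomolecules
(proteins, genes, metabolites), whose edges carry strictly positive costs
derived from interaction confidence, and whose nodes may carry non-negative
prizes derived from experimental measurements (differential expression,
phosphorylation, mutation counts). Nodes with a positive prize are called
*terminals*; prize-less nodes that nevertheless enter a solution are
*Steiner* nodes.

Because highly connected hub proteins would otherwise be pulled into almost
any solution, raw prizes are penalized by node degree before solving:

    p'_v = max(0, beta * p_v - mu * degree(v))

where ``beta`` rescales prizes relative to edge costs and ``mu`` is the hub
penalty. The degree is taken in the full template network, never in a
candidate solution, and negative penalized prizes are clamped to zero (a
negative prize would act as an undefined extra node cost). The penalty is
applied after ``beta`` scaling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx

__all__ = [
    "MU_RECOMMENDED_RANGE",
    "EdgeTableError",
    "PrizeError",
    "SolverParams",
    "Interactome",
    "PrizedInteractome",
    "canonical_edge",
    "construct_interactome",
    "assign_prizes",
]

logger = logging.getLogger(__name__)

#: Recommended hub-penalty (mu) range for biological networks. Values outside
#: this range (including 0, which disables the penalty) are legal; callers may
#: warn but must not reject.
MU_RECOMMENDED_RANGE = (1e-4, 5e-2)


class EdgeTableError(ValueError):
    """An edge table violates the input contract (bad cost, empty table)."""


class PrizeError(ValueError):
    """A prize table cannot be mapped onto the graph."""


def canonical_edge(u: str, v: str) -> tuple[str, str]:
    """Return the unordered pair (u, v) in canonical (sorted) order."""
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class SolverParams:
    """Parameters of the PCSF objective.

    Attributes
    ----------
    beta:
        Prize scaling factor (> 0); tunes node prizes relative to edge costs.
    w:
        Per-tree penalty (> 0), often written omega; each connected component
        of the solution forest pays ``w``, so larger values favour fewer,
        larger trees.
    mu:
        Hub penalty (>= 0); each node's prize is reduced by ``mu * degree``.
    """

    beta: float = 1.0
    w: float = 2.0
    mu: float = 0.0005

    def __post_init__(self) -> None:
        if not (self.beta > 0 and math.isfinite(self.beta)):
            raise ValueError(f"beta must be a positive real, got {self.beta!r}")
        if not (self.w > 0 and math.isfinite(self.w)):
            raise ValueError(f"w must be a positive real, got {self.w!r}")
        if not (self.mu >= 0 and math.isfinite(self.mu)):
            raise ValueError(f"mu must be a non-negative real, got {self.mu!r}")


class Interactome:
    """A simple undirected template network with edge costs and node prizes.

    Node identifiers are case-sensitive opaque strings. Edge costs are
    strictly positive; every node has a prize (0 unless assigned).
    Backed by a :class:`networkx.Graph` with ``cost`` edge attributes and
    ``prize`` node attributes.
    """

    def __init__(self, graph: nx.Graph):
        for u, v, data in graph.edges(data=True):
            if u == v:
                raise EdgeTableError(f"self-loop on node {u!r}")
            c = data.get("cost")
            if c is None or not (c > 0 and math.isfinite(c)):
                raise EdgeTableError(f"edge {u!r}-{v!r} has non-positive cost {c!r}")
        for v, data in graph.nodes(data=True):
            data.setdefault("prize", 0.0)
            if data["prize"] < 0:
                raise PrizeError(f"node {v!r} has negative prize {data['prize']!r}")
        self._g = graph

    # -- basic accessors -------------------------------------------------
    @property
    def graph(self) -> nx.Graph:
        """The underlying networkx graph (treat as read-only)."""
        return self._g

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._g.nodes)

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        return frozenset(canonical_edge(u, v) for u, v in self._g.edges)

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def cost(self, u: str, v: str) -> float:
        return self._g.edges[u, v]["cost"]

    def prize(self, v: str) -> float:
        return self._g.nodes[v].get("prize", 0.0)

    @property
    def prizes(self) -> dict[str, float]:
        """Raw prize of every node (0 for non-terminals)."""
        return {v: d.get("prize", 0.0) for v, d in self._g.nodes(data=True)}

    @property
    def terminals(self) -> frozenset[str]:
        """Nodes with a positive raw prize."""
        return frozenset(v for v, d in self._g.nodes(data=True) if d.get("prize", 0.0) > 0)

    def degree(self, v: str) -> int:
        return self._g.degree[v]

    # -- construction helpers -------------------------------------------
    def with_prizes(self, prizes: Mapping[str, float]) -> "Interactome":
        """Return a copy of this interactome with prizes replaced by *prizes*.

        Nodes absent from *prizes* get prize 0. Keys absent from the graph
        are ignored by this low-level helper (use :func:`assign_prizes` for
        validated mapping).
        """
        g = self._g.copy()
        for v in g.nodes:
            g.nodes[v]["prize"] = 0.0
        for v, p in prizes.items():
            if v in g:
                if p < 0:
                    raise PrizeError(f"negative prize {p!r} for node {v!r}")
                g.nodes[v]["prize"] = float(p)
        return Interactome(g)

    def edge_rows(self) -> Iterator[tuple[str, str, float]]:
        """Yield (node_a, node_b, cost) rows in canonical sorted order."""
        for u, v in sorted(self.edges):
            yield u, v, self.cost(u, v)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Interactome):
            return NotImplemented
        if self.nodes != other.nodes or self.edges != other.edges:
            return False
        return all(
            self.cost(u, v) == other.cost(u, v) for u, v in self.edges
        ) and self.prizes == other.prizes

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Interactome({self.n_nodes} nodes, {self.n_edges} edges, {len(self.terminals)} terminals)"


def construct_interactome(edge_rows: Iterable[Sequence]) -> Interactome:
    """Build an :class:`Interactome` from (node_a, node_b, cost) rows.

    Duplicate undirected edges are collapsed keeping the minimum cost (the
    most confident interaction wins); self-loops are dropped with a logged
    count. A non-positive or unparseable cost aborts the whole row set.

    Raises
    ------
    EdgeTableError
        If the table is empty, or any row has a non-numeric or non-positive
        cost (the message names the offending row).
    """
    g = nx.Graph()
    n_self_loops = 0
    n_rows = 0
    for lineno, row in enumerate(edge_rows, start=1):
        if len(row) < 3:
            raise EdgeTableError(f"row {lineno}: expected (node_a, node_b, cost), got {row!r}")
        a, b = str(row[0]), str(row[1])
        try:
            cost = float(row[2])
        except (TypeError, ValueError):
            raise EdgeTableError(f"row {lineno}: non-numeric cost {row[2]!r}") from None
        if not (cost > 0 and math.isfinite(cost)):
            raise EdgeTableError(f"row {lineno}: cost must be > 0, got {cost!r}")
        n_rows += 1
        if a == b:
            n_self_loops += 1
            continue
        if g.has_edge(a, b):
            if cost < g.edges[a, b]["cost"]:
                g.edges[a, b]["cost"] = cost
        else:
            g.add_edge(a, b, cost=cost)
    if n_rows == 0:
        raise EdgeTableError("empty edge table")
    if n_self_loops:
        logger.info("dropped %d self-loop row(s)", n_self_loops)
    if g.number_of_edges() == 0:
        raise EdgeTableError("edge table contains only self-loops")
    return Interactome(g)


@dataclass(eq=True)
class PrizedInteractome:
    """An interactome together with hub-penalized, beta-scaled prizes.

    ``penalized_prize[v] = max(0, beta * p_v - mu * degree(v))`` for every
    node, where ``degree`` is taken in the full template network.
    ``terminals`` are the supplied-prize nodes present in the graph (raw
    prize > 0); a terminal may still have penalized prize 0 if the hub
    penalty swallowed it.
    """

    base: Interactome
    params: SolverParams
    penalized_prize: dict[str, float] = field(repr=False)
    degree: dict[str, int] = field(repr=False)
    terminals: frozenset[str] = frozenset()

    @property
    def graph(self) -> nx.Graph:
        return self.base.graph

    def cost(self, u: str, v: str) -> float:
        return self.base.cost(u, v)

    @property
    def nodes(self) -> frozenset[str]:
        return self.base.nodes

    @property
    def positive_terminals(self) -> frozenset[str]:
        """Terminals whose penalized prize is still positive."""
        return frozenset(v for v in self.terminals if self.penalized_prize[v] > 0)

    @property
    def total_penalized_prize(self) -> float:
        return sum(self.penalized_prize.values())

    def reweighted(self, new_costs: Mapping[tuple[str, str], float]) -> "PrizedInteractome":
        """Copy with edge costs replaced (used by cost randomization)."""
        g = self.base.graph.copy()
        for (u, v), c in new_costs.items():
            g.edges[u, v]["cost"] = float(c)
        return PrizedInteractome(
            base=Interactome(g),
            params=self.params,
            penalized_prize=dict(self.penalized_prize),
            degree=dict(self.degree),
            terminals=self.terminals,
        )


def assign_prizes(
    g: Interactome,
    prizes: Mapping[str, float],
    params: SolverParams,
) -> PrizedInteractome:
    """Map raw prizes onto the graph and apply beta scaling + hub penalty.

    Prize keys absent from the graph are logged and dropped (identifier
    mismatch between data and network is routine). Nodes without a supplied
    prize get 0.

    Raises
    ------
    PrizeError
        If any prize is negative, or *no* supplied prize id is present in
        the graph (nothing to anchor a solution).
    """
    for v, p in prizes.items():
        if p < 0:
            raise PrizeError(f"negative prize {p!r} for node {v!r}")
    present = {v: float(p) for v, p in prizes.items() if v in g.graph}
    dropped = sorted(set(prizes) - set(present))
    if dropped:
        logger.info(
            "dropped %d prize id(s) absent from the graph (first few: %s)",
            len(dropped),
            ", ".join(dropped[:5]),
        )
    if prizes and not present:
        raise PrizeError("no supplied prize id is present in the graph")

    prized = g.with_prizes(present)
    degree = {v: g.degree(v) for v in g.graph.nodes}
    penalized = {
        v: max(0.0, params.beta * prized.prize(v) - params.mu * degree[v])
        for v in g.graph.nodes
    }
    terminals = frozenset(v for v, p in present.items() if p > 0)
    return PrizedInteractome(
        base=prized,
        params=params,
        penalized_prize=penalized,
        degree=degree,
        terminals=terminals,
    )
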