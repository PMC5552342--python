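"""Prize-collecting Steiner forest solvers.

Given a prized interactome, find a forest ``G' = (V', E')`` minimizing

    F(G') = sum_{e in E'} c_e  +  sum_{v not in V'} p'_v  +  w * k

where ``p'`` are the (already beta-scaled, hub-penalized) node prizes, ``k``
is the number of trees in the forest and ``w`` the per-tree penalty. The
problem is NP-hard, so two routes are provided:

``solve_pcsf``
    A fast heuristic: an artificial root is joined to every positive-prize
    terminal with an edge of cost ``w`` — this reduces the forest problem to
    a rooted prize-collecting Steiner *tree* problem in which every surviving
    root edge charges exactly ``w`` per tree. The rooted instance is solved
    by Goemans–Williamson moat growth followed by strong pruning (an exact
    dynamic program on the grown tree), a deterministic local-improvement
    pass, and a final comparison against the trivial solutions (empty
    forest, isolated terminals).

``solve_exact``
    An exhaustive oracle for small instances (at most 20 edges): enumerate
    every edge subset that induces a forest plus every profitable isolated
    node, returning the global optimum with a deterministic tie-break. This
    is the test authority against which the heuristic is validated.

All tie-breaks are deterministic via sorted node/edge identifiers, so fixed
inputs give bit-identical outputs.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .graph_model import PrizedInteractome, SolverParams, canonical_edge

__all__ = [
    "Forest",
    "StructuralError",
    "InstanceTooLargeError",
    "objective",
    "make_forest",
    "validate_forest",
    "solve_exact",
    "solve_pcsf",
    "EXACT_EDGE_LIMIT",
]

logger = logging.getLogger(__name__)

#: Hard guard for the exhaustive oracle (2^20 edge subsets).
EXACT_EDGE_LIMIT = 20

_TOL = 1e-9
_TIE = 1e-12


class StructuralError(ValueError):
    """A forest refers to nodes or edges absent from the graph."""


class InstanceTooLargeError(ValueError):
    """The instance exceeds the exhaustive oracle's size guard."""


@dataclass(frozen=True)
class Forest:
    """A candidate solution: an acyclic subgraph with ``k`` trees.

    Invariants (checked by :func:`validate_forest`): ``|E'| = |V'| - k``;
    every edge endpoint lies in ``nodes``; ``objective`` is recomputable
    from the fields to within 1e-9; no leaf is a zero-prize (Steiner) node.
    """

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    k: int
    objective: float
    steiner_nodes: frozenset[str]
    terminal_nodes: frozenset[str]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def is_empty(self) -> bool:
        return not self.nodes


# ---------------------------------------------------------------------------
# objective and construction
# ---------------------------------------------------------------------------

def objective(g: PrizedInteractome, f: Forest, params: SolverParams) -> float:
    """Recompute the PCSF objective of *f* over *g* (pure function).

    Returns the sum of edge costs in the forest, penalized prizes of nodes
    left out, and ``w`` per tree.

    Raises
    ------
    StructuralError
        If *f* contains a node or edge absent from *g*.
    """
    gnodes = g.nodes
    missing = f.nodes - gnodes
    if missing:
        raise StructuralError(f"forest node(s) not in graph: {sorted(missing)[:5]}")
    graph = g.graph
    cost_sum = 0.0
    for u, v in sorted(f.edges):
        if not graph.has_edge(u, v):
            raise StructuralError(f"forest edge not in graph: {(u, v)}")
        cost_sum += graph.edges[u, v]["cost"]
    forgone = sum(p for v, p in g.penalized_prize.items() if v not in f.nodes)
    return cost_sum + forgone + params.w * f.k


def _count_components(nodes: Iterable[str], edges: Iterable[tuple[str, str]]) -> int:
    parent: dict[str, str] = {v: v for v in nodes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    k = len(parent)
    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            k -= 1
    return k


def make_forest(
    g: PrizedInteractome,
    nodes: Iterable[str],
    edges: Iterable[tuple[str, str]],
    params: SolverParams,
) -> Forest:
    """Assemble a :class:`Forest` from node/edge sets, computing k and the
    objective; edges are canonicalized."""
    node_set = frozenset(nodes)
    edge_set = frozenset(canonical_edge(u, v) for u, v in edges)
    k = _count_components(node_set, edge_set)
    terminal_nodes = node_set & g.terminals
    proto = Forest(
        nodes=node_set,
        edges=edge_set,
        k=k,
        objective=0.0,
        steiner_nodes=node_set - terminal_nodes,
        terminal_nodes=terminal_nodes,
    )
    obj = objective(g, proto, params)
    return Forest(
        nodes=node_set,
        edges=edge_set,
        k=k,
        objective=obj,
        steiner_nodes=node_set - terminal_nodes,
        terminal_nodes=terminal_nodes,
    )


def validate_forest(f: Forest, g: PrizedInteractome) -> list[str]:
    """Return a list of invariant violations (empty list means valid)."""
    violations: list[str] = []
    gnodes = g.nodes
    graph = g.graph
    for v in sorted(f.nodes - gnodes):
        violations.append(f"node not in graph: {v}")
    degree: dict[str, int] = {v: 0 for v in f.nodes}
    for u, v in sorted(f.edges):
        if u not in f.nodes or v not in f.nodes:
            violations.append(f"edge endpoint not in V': {(u, v)}")
            continue
        if not graph.has_edge(u, v):
            violations.append(f"edge not in graph: {(u, v)}")
            continue
        degree[u] += 1
        degree[v] += 1
    ok_edges = [e for e in f.edges if e[0] in f.nodes and e[1] in f.nodes]
    k_actual = _count_components(f.nodes, ok_edges)
    if len(ok_edges) != len(f.nodes) - f.k:
        violations.append(f"acyclicity: |E'| != |V'| - k ({len(ok_edges)} != {len(f.nodes)} - {f.k})")
    elif k_actual != f.k:
        violations.append(f"component count mismatch: stored k={f.k}, actual {k_actual}")
    if not violations:
        expected = objective(g, f, g.params)
        if abs(expected - f.objective) > _TOL:
            violations.append(
                f"objective mismatch: stored {f.objective!r}, recomputed {expected!r}"
            )
        for v, d in degree.items():
            if d == 1 and g.penalized_prize.get(v, 0.0) <= 0.0:
                violations.append(f"Steiner leaf (degree-1 node with zero prize): {v}")
    if f.steiner_nodes | f.terminal_nodes != f.nodes or f.steiner_nodes & f.terminal_nodes:
        violations.append("steiner/terminal partition does not partition V'")
    return violations


# ---------------------------------------------------------------------------
# exhaustive oracle
# ---------------------------------------------------------------------------

def solve_exact(g: PrizedInteractome, params: SolverParams) -> Forest:
    """Global optimum by exhaustive enumeration (instances with <= 20 edges).

    Enumerates every acyclic edge subset (depth-first with cycle pruning via
    union-find) plus, for nodes untouched by the chosen edges, the optimal
    set of isolated prize nodes (include a singleton tree iff ``p' > w``; at
    exact equality the node is excluded, giving the lexicographically
    smaller node list). Ties on the objective (within 1e-12) are broken by
    the lexicographically smallest sorted edge list, then node list.
    """
    graph = g.graph
    edges = sorted(
        (canonical_edge(u, v) for u, v in graph.edges),
    )
    m = len(edges)
    if m > EXACT_EDGE_LIMIT:
        raise InstanceTooLargeError(
            f"{m} edges exceeds the exhaustive-search guard of {EXACT_EDGE_LIMIT}"
        )
    nodes = sorted(graph.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    cost = [graph.edges[u, v]["cost"] for u, v in edges]
    eidx = [(idx[u], idx[v]) for u, v in edges]
    p = [g.penalized_prize[v] for v in nodes]
    total_p = sum(p)
    w = params.w

    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            x = parent[x]
        return x

    touch = [0] * n  # incident chosen-edge count per node
    chosen: list[int] = []
    best: list = [math.inf, None, None]  # objective, edge tuple, node tuple

    def evaluate() -> None:
        touched = [i for i in range(n) if touch[i]]
        prize_in = sum(p[i] for i in touched)
        k_edges = len(touched) - len(chosen)
        singles = [i for i in range(n) if not touch[i] and p[i] > w]
        obj = (
            sum(cost[i] for i in chosen)
            + (total_p - prize_in - sum(p[i] for i in singles))
            + w * (k_edges + len(singles))
        )
        if obj < best[0] - _TIE:
            best[0] = obj
            best[1] = tuple(edges[i] for i in chosen)
            best[2] = tuple(sorted(nodes[i] for i in touched + singles))
        elif obj <= best[0] + _TIE:
            cand_e = tuple(edges[i] for i in chosen)
            cand_n = tuple(sorted(nodes[i] for i in touched + singles))
            if (cand_e, cand_n) < (best[1], best[2]):
                best[0] = min(best[0], obj)
                best[1], best[2] = cand_e, cand_n

    def rec(i: int) -> None:
        if i == m:
            evaluate()
            return
        rec(i + 1)  # exclude edge i
        a, b = eidx[i]
        ra, rb = find(a), find(b)
        if ra == rb:
            return  # including edge i closes a cycle
        parent[ra] = rb
        touch[a] += 1
        touch[b] += 1
        chosen.append(i)
        rec(i + 1)
        chosen.pop()
        touch[a] -= 1
        touch[b] -= 1
        parent[ra] = ra

    rec(0)
    return make_forest(g, best[2], best[1], params)


# ---------------------------------------------------------------------------
# Goemans–Williamson heuristic
# ---------------------------------------------------------------------------

_ROOT = "\x00__root__"  # sorts before any printable identifier


def _gw_grow(
    aug_edges: list[tuple[str, str, float]],
    potentials: dict[str, float],
    root: str,
) -> list[int]:
    """Goemans–Williamson moat growth on the rooted augmented graph.

    Every node starts as its own cluster; a cluster is *active* while it
    does not contain the root and has prize potential left. All active
    moats grow at unit rate; an edge goes tight when the moats on its two
    sides have jointly paid its cost, merging the clusters; a cluster dies
    when its potential is exhausted. Returns indices of tight (merge) edges.
    """
    parent: dict[str, str] = {v: v for v in potentials}
    size: dict[str, int] = {v: 1 for v in potentials}
    min_node: dict[str, str] = {v: v for v in potentials}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    active: dict[str, float] = {
        v: pot for v, pot in potentials.items() if v != root and pot > _TIE
    }
    load = [0.0] * len(aug_edges)
    merged: list[int] = []

    while active:
        # candidate edge event
        best_dt = math.inf
        best_edge = -1
        best_key: tuple[str, str] | None = None
        for i, (u, v, c) in enumerate(aug_edges):
            ru, rv = find(u), find(v)
            if ru == rv:
                continue
            rate = (ru in active) + (rv in active)
            if rate == 0:
                continue
            dt = max(0.0, (c - load[i]) / rate)
            key = (u, v)
            if dt < best_dt - _TIE or (dt <= best_dt + _TIE and (best_key is None or key < best_key)):
                best_dt, best_edge, best_key = dt, i, key
        # candidate death event
        death_dt = math.inf
        death_rep = None
        for r, pot in active.items():
            key = min_node[r]
            if pot < death_dt - _TIE or (pot <= death_dt + _TIE and (death_rep is None or key < min_node[death_rep])):
                death_dt, death_rep = pot, r
        if best_edge < 0 and death_rep is None:  # pragma: no cover - defensive
            break
        take_edge = best_edge >= 0 and best_dt <= death_dt + _TIE
        dt = best_dt if take_edge else death_dt
        # advance time
        for i, (u, v, _) in enumerate(aug_edges):
            ru, rv = find(u), find(v)
            if ru == rv:
                continue
            rate = (ru in active) + (rv in active)
            if rate:
                load[i] += dt * rate
        for r in list(active):
            active[r] -= dt
        if take_edge:
            u, v, _ = aug_edges[best_edge]
            ru, rv = find(u), find(v)
            merged.append(best_edge)
            pot = active.pop(ru, 0.0) + active.pop(rv, 0.0)
            # union by size
            if size[ru] < size[rv]:
                ru, rv = rv, ru
            parent[rv] = ru
            size[ru] += size[rv]
            min_node[ru] = min(min_node[ru], min_node[rv])
            if find(root) == ru:
                pass  # the cluster containing the root never grows
            elif pot > _TIE:
                active[ru] = pot
        else:
            assert death_rep is not None
            del active[death_rep]
    return merged


def _prune_forest(
    nodes: set[str],
    edges: set[tuple[str, str]],
    prize: dict[str, float],
    cost: dict[tuple[str, str], float],
    w: float,
) -> tuple[set[str], set[tuple[str, str]]]:
    """Exact optimal subforest *within* a given forest, by tree DP.

    For each tree of the input forest, computes the forest contained in its
    edges that maximizes collected prize minus edge costs minus ``w`` per
    resulting component. Two values per node:

    - ``A(v)``: best profit in v's subtree with v included and its component
      left open (its ``w`` charge deferred to whoever closes it);
    - ``B(v)``: best unconstrained profit (components all closed).

    Subsumes strong pruning and edge splitting; ties prefer exclusion, so
    no zero-prize leaf and no zero-gain edge survives.
    """
    adj: dict[str, list[tuple[str, float]]] = {v: [] for v in nodes}
    for u, v in edges:
        c = cost[(u, v)]
        adj[u].append((v, c))
        adj[v].append((u, c))
    keep_nodes: set[str] = set()
    keep_edges: set[tuple[str, str]] = set()
    visited: set[str] = set()
    for start in sorted(nodes):
        if start in visited:
            continue
        # iterative post-order rooted at start
        order: list[str] = []
        par: dict[str, tuple[str, float] | None] = {start: None}
        stack = [start]
        visited.add(start)
        while stack:
            v = stack.pop()
            order.append(v)
            for nbr, c in sorted(adj[v]):
                if nbr not in visited:
                    visited.add(nbr)
                    par[nbr] = (v, c)
                    stack.append(nbr)
        children: dict[str, list[tuple[str, float]]] = {v: [] for v in order}
        for v in order[1:]:
            pv, c = par[v]  # type: ignore[misc]
            children[pv].append((v, c))
        A: dict[str, float] = {}
        B: dict[str, float] = {}
        connect: dict[str, list[str]] = {}  # children joined through v in A(v)
        close: dict[str, bool] = {}  # B(v) realized as A(v) - w?
        for v in reversed(order):
            a = prize.get(v, 0.0)
            joined: list[str] = []
            for child, c in children[v]:
                if A[child] - c > B[child] + _TIE:
                    a += A[child] - c
                    joined.append(child)
                else:
                    a += B[child]
            A[v] = a
            connect[v] = joined
            b_open = a - w
            b_drop = sum(B[child] for child, _ in children[v])
            close[v] = b_open > b_drop + _TIE
            B[v] = b_open if close[v] else b_drop
        # reconstruct: (node, mode) where mode "B" = unconstrained, "A" = included
        work: list[tuple[str, str]] = [(start, "B")]
        while work:
            v, mode = work.pop()
            if mode == "B" and not close[v]:
                for child, _ in children[v]:
                    work.append((child, "B"))
                continue
            keep_nodes.add(v)
            joined = set(connect[v])
            for child, _ in children[v]:
                if child in joined:
                    keep_edges.add(canonical_edge(v, child))
                    work.append((child, "A"))
                else:
                    work.append((child, "B"))
    return keep_nodes, keep_edges


def _attach_gain(
    g: PrizedInteractome,
    forest_nodes: set[str],
    source: str,
) -> tuple[float, list[str]]:
    """Best gain from attaching *source* to the current forest via a
    cheapest path (prizes of newly added nodes offset edge costs).

    Uses Dijkstra over edge costs from *source*, stopping expansion at
    forest nodes. Returns (gain, path including the forest contact node);
    gain is -inf if the forest is unreachable.
    """
    pp = g.penalized_prize
    graph = g.graph
    dist = {source: 0.0}
    prev: dict[str, str] = {}
    heap = [(0.0, source)]
    done: set[str] = set()
    best_gain = -math.inf
    best_contact = None
    while heap:
        d, v = heapq.heappop(heap)
        if v in done:
            continue
        done.add(v)
        if v in forest_nodes:
            # prizes collected along the path (excluding the contact node)
            path = [v]
            x = v
            while x != source:
                x = prev[x]
                path.append(x)
            gain = -d + sum(pp[x] for x in path[1:])
            if gain > best_gain:
                best_gain, best_contact = gain, v
            continue  # do not expand through the forest
        for nbr in graph.neighbors(v):
            nd = d + graph.edges[v, nbr]["cost"]
            if nd < dist.get(nbr, math.inf) - _TIE:
                dist[nbr] = nd
                prev[nbr] = v
                heapq.heappush(heap, (nd, nbr))
    if best_contact is None:
        return -math.inf, []
    path = [best_contact]
    x = best_contact
    while x != source:
        x = prev[x]
        path.append(x)
    return best_gain, path


def _components(
    nodes: set[str], edges: set[tuple[str, str]]
) -> list[set[str]]:
    adj: dict[str, set[str]] = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    comps: list[set[str]] = []
    seen: set[str] = set()
    for start in sorted(nodes):
        if start in seen:
            continue
        comp = {start}
        seen.add(start)
        stack = [start]
        while stack:
            x = stack.pop()
            for nbr in adj[x]:
                if nbr not in seen:
                    seen.add(nbr)
                    comp.add(nbr)
                    stack.append(nbr)
        comps.append(comp)
    return comps


def _merge_gain(
    g: PrizedInteractome,
    comp: set[str],
    others: set[str],
    w: float,
) -> tuple[float, list[str]]:
    """Gain from joining tree *comp* to another tree (saves one ``w``,
    pays the cheapest connecting path net of new node prizes)."""
    pp = g.penalized_prize
    graph = g.graph
    dist = {v: 0.0 for v in comp}
    prev: dict[str, str] = {}
    heap = [(0.0, v) for v in sorted(comp)]
    heapq.heapify(heap)
    done: set[str] = set()
    best = (-math.inf, "")
    while heap:
        d, v = heapq.heappop(heap)
        if v in done:
            continue
        done.add(v)
        if v in others:
            path = [v]
            x = v
            while x not in comp:
                x = prev[x]
                path.append(x)
            gain = w - d + sum(pp[x] for x in path[1:-1] if x not in others)
            if gain > best[0]:
                best = (gain, v)
            continue
        for nbr in graph.neighbors(v):
            if nbr in comp:
                continue
            nd = d + graph.edges[v, nbr]["cost"]
            if nd < dist.get(nbr, math.inf) - _TIE:
                dist[nbr] = nd
                prev[nbr] = v
                heapq.heappush(heap, (nd, nbr))
    if not math.isfinite(best[0]):
        return -math.inf, []
    path = [best[1]]
    x = best[1]
    while x not in comp:
        x = prev[x]
        path.append(x)
    return best[0], path


def _candidate_moves(
    g: PrizedInteractome,
    params: SolverParams,
    pos_terminals: list[str],
    nodes: set[str],
    edges: set[tuple[str, str]],
    min_gain: float,
) -> list[tuple[float, list[str]]]:
    """Enumerate expansion moves (singleton, terminal attachment, tree
    merge) with immediate gain above *min_gain*, best first; ties broken by
    the path's node sequence."""
    pp = g.penalized_prize
    w = params.w
    moves: list[tuple[float, list[str]]] = []
    for t in pos_terminals:
        if t in nodes:
            continue
        if pp[t] - w > min_gain:
            moves.append((pp[t] - w, [t]))
        if nodes:
            gain, path = _attach_gain(g, nodes, t)
            if gain > min_gain:
                moves.append((gain, path))
    comps = _components(nodes, edges)
    if len(comps) >= 2:
        for comp in comps:
            gain, path = _merge_gain(g, comp, nodes - comp, w)
            if gain > min_gain:
                moves.append((gain, path))
    moves.sort(key=lambda m: (-m[0], m[1]))
    return moves


def _respan(
    g: PrizedInteractome, nodes: set[str]
) -> set[tuple[str, str]]:
    """Minimum spanning forest of the subgraph induced by *nodes*
    (deterministic Kruskal: ties broken by edge identity)."""
    graph = g.graph
    cand = sorted(
        (graph.edges[u, v]["cost"], canonical_edge(u, v))
        for u, v in graph.subgraph(nodes).edges
    )
    parent = {v: v for v in nodes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    out: set[tuple[str, str]] = set()
    for _, (u, v) in cand:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            out.add((u, v))
    return out


def _improve(
    g: PrizedInteractome,
    params: SolverParams,
    pos_terminals: list[str],
    nodes: set[str],
    edges: set[tuple[str, str]],
    prune,
) -> tuple[set[str], set[tuple[str, str]]]:
    """Greedy best-first improvement to a fixed point: repeatedly apply the
    highest-gain positive move and re-prune."""
    for _ in range(2 * len(pos_terminals) + 4):
        moves = _candidate_moves(g, params, pos_terminals, nodes, edges, min_gain=_TOL)
        if not moves:
            break
        _, path = moves[0]
        nodes.update(path)
        for a, b in zip(path, path[1:]):
            edges.add(canonical_edge(a, b))
        nodes, edges = prune(nodes, edges)
    return nodes, edges


def solve_pcsf(g: PrizedInteractome, params: SolverParams) -> Forest:
    """Fast heuristic solution of the PCSF objective.

    Guarantees: the returned forest is valid (acyclic, consistent k and
    objective), is never worse than the empty forest or the best set of
    isolated terminals, and contains no zero-prize (Steiner) leaf.

    If no node has a positive penalized prize (e.g. ``mu`` swallowed every
    prize) the empty forest is returned with a warning.
    """
    graph = g.graph
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot solve on an empty graph")
    pp = g.penalized_prize
    w = params.w
    pos_terminals = sorted(v for v in graph.nodes if pp[v] > 0)
    if not pos_terminals:
        logger.warning("no node has positive penalized prize; returning the empty forest")
        return make_forest(g, [], [], params)

    # rooted augmented instance: root--terminal edges of cost w
    aug_edges = [
        (*canonical_edge(u, v), graph.edges[u, v]["cost"]) for u, v in graph.edges
    ]
    aug_edges.sort()
    aug_edges = [(_ROOT, t, w) for t in pos_terminals] + aug_edges
    potentials = {v: pp[v] for v in graph.nodes}
    potentials[_ROOT] = 0.0

    merged = _gw_grow(aug_edges, potentials, _ROOT)

    # the grown forest, with the artificial root and its edges stripped
    nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    for i in merged:
        u, v, _ = aug_edges[i]
        if _ROOT in (u, v):
            continue
        nodes.update((u, v))
        edges.add(canonical_edge(u, v))
    nodes.update(t for t in pos_terminals if pp[t] > w)  # sure-win singletons
    cost_of = {
        canonical_edge(u, v): graph.edges[u, v]["cost"] for u, v in graph.edges
    }

    def prune(ns: set[str], es: set[tuple[str, str]]):
        return _prune_forest(ns, es, pp, cost_of, w)

    nodes, edges = prune(nodes, edges)
    nodes, edges = _improve(g, params, pos_terminals, nodes, edges, prune)

    # depth-1 lookahead: a merge or attachment that does not pay for itself
    # may still enable profitable follow-up moves (e.g. joining two trees
    # through a region with collectable side prizes); tentatively apply each
    # near-miss move, re-improve, and keep the result only if it wins
    candidate = make_forest(g, nodes, edges, params)
    for _ in range(4):
        moves = _candidate_moves(g, params, pos_terminals, nodes, edges, min_gain=-w)
        better = None
        for _, path in moves:
            ns, es = set(nodes), set(edges)
            ns.update(path)
            for a, b in zip(path, path[1:]):
                es.add(canonical_edge(a, b))
            # improve before pruning so follow-up moves can justify the
            # tentative expansion; prune once at the end
            ns, es = _improve(g, params, pos_terminals, ns, es, prune)
            ns, es = prune(ns, es)
            f2 = make_forest(g, ns, es, params)
            if f2.objective < candidate.objective - _TOL:
                better = (f2, ns, es)
                break
        if better is None:
            break
        candidate, nodes, edges = better[0], better[1], better[2]

    # polish: re-span the selected nodes with a minimum spanning forest
    # (the grown tree's edges need not be cost-minimal for its node set),
    # and try deleting each Steiner node (a connector may be beatable by a
    # cheaper detour through a node outside the current solution)
    def _polished(trial_nodes: set[str]):
        ns = set(trial_nodes)
        es = _respan(g, ns)
        ns, es = prune(ns, es)
        ns, es = _improve(g, params, pos_terminals, ns, es, prune)
        return make_forest(g, ns, es, params)

    for _ in range(len(candidate.steiner_nodes) + 2):
        trials = [set(nodes)]
        trials += [set(nodes) - {s} for s in sorted(candidate.steiner_nodes)]
        better = None
        for trial in trials:
            f2 = _polished(trial)
            if f2.objective < candidate.objective - _TOL:
                better = f2
                break
        if better is None:
            break
        candidate = better
        nodes, edges = set(better.nodes), set(better.edges)

    # never worse than the trivial solutions
    trivials = [
        make_forest(g, [], [], params),
        make_forest(g, [v for v in pos_terminals if pp[v] > w], [], params),
    ]
    best = candidate
    for t in trivials:
        if t.objective < best.objective - _TIE:
            best = t
    return best
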