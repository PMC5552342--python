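"""Deterministic generators for test networks and worked examples.

The solver's intended inputs are sparse interactomes with heavy-tailed
degree distributions (a few hubs, many low-degree nodes) onto which a small
set of high-scoring nodes — ideally forming a connected dysregulated module
— has been mapped. This module builds such instances from a seed:

* ``generate_background`` — a connected preferential-attachment graph with
  i.i.d. edge costs (uniform on (0.1, 1.0] by default, the scale of
  confidence-derived interaction costs);
* ``plant_module`` — a randomly grown connected subtree of high-prize
  nodes (the ground-truth module the solver should recover), plus sparse
  low-prize background terminals emulating measurement noise.

Also defined here are four small named fixtures used throughout the test
suite and the documentation: a 6-node toy instance, a hub-penalty
instance, a two-cluster instance for the per-tree penalty, and the
planted-module recovery instance. All outputs are bit-reproducible from
the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .graph_model import Interactome

__all__ = [
    "FixtureSpec",
    "generate_background",
    "plant_module",
    "toy1_rows",
    "toy1_prizes",
    "two_cluster_rows",
    "two_cluster_prizes",
    "hub_rows",
    "hub_prizes",
    "recovery_instance",
    "write_tsv_fixture",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a generated instance.

    ``n_nodes`` nodes wired by preferential attachment with ``m_attach``
    edges per new node; a planted connected module of ``module_size`` nodes
    with gamma-distributed prizes of mean ``module_prize_mean``; a fraction
    ``background_prize_rate`` of the remaining nodes get small background
    prizes of mean ``background_prize_mean``. Edge costs are uniform on
    (``cost_low``, ``cost_high``].
    """

    n_nodes: int = 300
    m_attach: int = 2
    module_size: int = 15
    module_prize_mean: float = 5.0
    background_prize_rate: float = 0.02
    background_prize_mean: float = 0.5
    cost_low: float = 0.1
    cost_high: float = 1.0
    seed: int = 7

    def __post_init__(self) -> None:
        if self.module_size >= self.n_nodes:
            raise ValueError("module_size must be smaller than n_nodes")
        if self.module_size < 0 or self.n_nodes < 2:
            raise ValueError("need n_nodes >= 2 and module_size >= 0")
        for name in ("module_prize_mean", "background_prize_mean", "background_prize_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0 < self.cost_low < self.cost_high):
            raise ValueError("need 0 < cost_low < cost_high")
        if not (1 <= self.m_attach < self.n_nodes):
            raise ValueError("need 1 <= m_attach < n_nodes")


def generate_background(spec: FixtureSpec) -> Interactome:
    """Connected heavy-tailed background graph with random edge costs.

    Uses Barabási–Albert preferential attachment (which is connected by
    construction and produces hubs) and i.i.d. uniform costs; fully
    deterministic under ``spec.seed``.
    """
    g = nx.barabasi_albert_graph(spec.n_nodes, spec.m_attach, seed=spec.seed)
    width = len(str(spec.n_nodes - 1))
    mapping = {i: f"N{i:0{width}d}" for i in g.nodes}
    g = nx.relabel_nodes(g, mapping)
    rng = np.random.default_rng(spec.seed)
    for u, v in sorted((min(a, b), max(a, b)) for a, b in g.edges):
        g.edges[u, v]["cost"] = float(
            rng.uniform(spec.cost_low, spec.cost_high)
        )
    for v in g.nodes:
        g.nodes[v]["prize"] = 0.0
    return Interactome(g)


def plant_module(
    g: Interactome,
    spec: FixtureSpec,
    rng: np.random.Generator,
) -> tuple[Interactome, frozenset[str]]:
    """Plant a connected high-prize module and sparse background prizes.

    Grows a random connected subtree of ``module_size`` nodes by seeded
    breadth-random expansion, assigns its nodes gamma(shape=2) prizes with
    mean ``module_prize_mean``, then gives a ``background_prize_rate``
    fraction of the remaining nodes gamma prizes with mean
    ``background_prize_mean``. Returns the prized interactome and the
    planted node set (ground truth for recovery scoring).

    Raises
    ------
    ValueError
        If no connected subtree of the requested size exists.
    """
    nodes = sorted(g.nodes)
    if spec.module_size > len(nodes):
        raise ValueError("module_size exceeds graph size")
    planted: set[str] = set()
    if spec.module_size > 0:
        start = nodes[rng.integers(len(nodes))]
        planted = {start}
        frontier = sorted(set(g.graph.neighbors(start)))
        while len(planted) < spec.module_size:
            if not frontier:
                raise ValueError(
                    f"cannot grow a connected module of size {spec.module_size}"
                )
            nxt = frontier[rng.integers(len(frontier))]
            planted.add(nxt)
            frontier = sorted(
                {n for v in planted for n in g.graph.neighbors(v)} - planted
            )
    prizes: dict[str, float] = {}
    for v in sorted(planted):
        prizes[v] = float(rng.gamma(2.0, spec.module_prize_mean / 2.0))
    rest = [v for v in nodes if v not in planted]
    n_bg = int(round(spec.background_prize_rate * len(rest)))
    if n_bg > 0:
        chosen = rng.choice(len(rest), size=n_bg, replace=False)
        for i in sorted(chosen):
            prizes[rest[i]] = float(rng.gamma(2.0, spec.background_prize_mean / 2.0))
    return g.with_prizes(prizes), frozenset(planted)


def recovery_instance(
    spec: FixtureSpec = FixtureSpec(),
) -> tuple[Interactome, frozenset[str]]:
    """The standard planted-module recovery instance (background +
    module + noise prizes) for the given spec; deterministic."""
    bg = generate_background(spec)
    rng = np.random.default_rng(spec.seed + 1)
    return plant_module(bg, spec, rng)


# ---------------------------------------------------------------------------
# small named fixtures
# ---------------------------------------------------------------------------

def toy1_rows() -> list[tuple[str, str, float]]:
    """A 6-node worked instance: two prize pockets joined by mid-cost
    edges, small enough for the exhaustive oracle."""
    return [
        ("A", "B", 0.2),
        ("B", "C", 0.3),
        ("C", "D", 0.8),
        ("D", "E", 0.2),
        ("E", "F", 0.4),
        ("B", "E", 0.9),
        ("A", "C", 0.6),
    ]


def toy1_prizes() -> dict[str, float]:
    return {"A": 3.0, "D": 2.5, "F": 1.5}


def two_cluster_rows() -> list[tuple[str, str, float]]:
    """Two cheap 3-node terminal chains joined by one expensive bridge;
    the per-tree penalty w decides whether the bridge is paid."""
    return [
        ("A1", "A2", 0.1),
        ("A2", "A3", 0.1),
        ("B1", "B2", 0.1),
        ("B2", "B3", 0.1),
        ("A3", "B1", 1.5),
    ]


def two_cluster_prizes() -> dict[str, float]:
    return {v: 3.0 for v in ("A1", "A2", "A3", "B1", "B2", "B3")}


def hub_rows() -> list[tuple[str, str, float]]:
    """Hub-penalty instance: a high-prize anchor module A1-A3, a prize-less
    hub X fanning out to ten modest terminals T01..T10, and ten decoy
    nodes D01..D10 wired to every terminal with expensive edges purely to
    inflate terminal degrees (degree 11 each)."""
    rows = [
        ("A1", "A2", 0.2),
        ("A2", "A3", 0.2),
        ("A1", "X", 0.1),
    ]
    terminals = [f"T{i:02d}" for i in range(1, 11)]
    decoys = [f"D{i:02d}" for i in range(1, 11)]
    rows += [("X", t, 0.1) for t in terminals]
    rows += [(t, d, 0.9) for t in terminals for d in decoys]
    return rows


def hub_prizes() -> dict[str, float]:
    prizes = {"A1": 5.0, "A2": 5.0, "A3": 5.0}
    prizes.update({f"T{i:02d}": 0.5 for i in range(1, 11)})
    return prizes


def write_tsv_fixture(
    out_dir: str | Path,
    name: str,
    rows: list[tuple[str, str, float]],
    prizes: dict[str, float],
) -> tuple[Path, Path]:
    """Write an edge table and a prize table in the pipeline's TSV formats;
    returns (edges_path, prizes_path)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    edges_path = out_dir / f"{name}_edges.tsv"
    prizes_path = out_dir / f"{name}_prizes.tsv"
    with open(edges_path, "w") as fh:
        fh.write("node_a\tnode_b\tcost\n")
        for a, b, c in rows:
            fh.write(f"{a}\t{b}\t{c:g}\n")
    with open(prizes_path, "w") as fh:
        fh.write("node\tprize\n")
        for v, p in sorted(prizes.items()):
            fh.write(f"{v}\t{p:g}\n")
    return edges_path, prizes_path
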