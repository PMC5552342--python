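"""Robustness analysis under randomized edge costs.

Edge costs in biological networks derive from noisy high-throughput
measurements, so a single PCSF solution can over-commit to particular
edges. The standard remedy is to re-solve the problem ``n`` times with
perturbed edge costs and merge the solutions: each node and edge is then
scored by the number of noisy runs in which it appeared, and elements with
high appearance counts are the robust core of the subnetwork.

The noise model is multiplicative uniform: each cost becomes
``c_e * (1 + u)`` with ``u ~ Uniform[-r, +r]`` drawn independently per
edge and per run. Multiplicative noise keeps the perturbation scale-free
across heterogeneous cost ranges; an additive variant
(``c_e + u * mean_cost``) can be selected by configuration. ``r < 1`` is
required so costs stay positive.

A single master seed spawns one independent random substream per run, so
results do not depend on execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph_model import PrizedInteractome, SolverParams, canonical_edge
from .solver import Forest, solve_pcsf

__all__ = ["RandConfig", "RobustForest", "perturb_costs", "pcsf_rand", "NOISE_MODELS"]

#: Supported noise strategies.
NOISE_MODELS = ("multiplicative", "additive")


@dataclass(frozen=True)
class RandConfig:
    """Configuration of the randomized re-solving loop.

    ``n`` noisy runs at noise level ``r`` (half-width of the uniform
    relative perturbation), seeded by ``seed``.
    """

    n: int = 10
    r: float = 0.1
    seed: int = 0
    noise: str = "multiplicative"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if not (0 <= self.r < 1):
            raise ValueError(
                f"r must lie in [0, 1) to keep perturbed costs positive, got {self.r}"
            )
        if self.noise not in NOISE_MODELS:
            raise ValueError(f"unknown noise model {self.noise!r}; choose from {NOISE_MODELS}")


@dataclass(frozen=True)
class RobustForest:
    """Union of ``n`` noisy solutions with appearance counts.

    ``node_count[v]`` / ``edge_count[e]`` give the number of runs (out of
    ``n``) whose solution contained the element; only elements appearing in
    at least one run are present. An edge can never appear without both
    endpoints, so ``edge_count[e] <= min(node_count[u], node_count[v])``.
    """

    n_runs: int
    union_nodes: frozenset[str]
    union_edges: frozenset[tuple[str, str]]
    node_count: tuple[tuple[str, int], ...]
    edge_count: tuple[tuple[tuple[str, str], int], ...]
    runs: tuple[Forest, ...] = field(repr=False)

    @property
    def node_counts(self) -> dict[str, int]:
        return dict(self.node_count)

    @property
    def edge_counts(self) -> dict[tuple[str, str], int]:
        return dict(self.edge_count)

    @property
    def objectives(self) -> list[float]:
        """Per-run objective values."""
        return [f.objective for f in self.runs]


def perturb_costs(
    g: PrizedInteractome,
    r: float,
    rng: np.random.Generator,
    noise: str = "multiplicative",
) -> PrizedInteractome:
    """Return a copy of *g* with every edge cost independently perturbed.

    Multiplicative (default): ``c -> c * (1 + u)``, ``u ~ U[-r, r]``.
    Additive: ``c -> max(c + u * c_mean, eps)`` with ``c_mean`` the mean
    template cost. Prizes are untouched; the input graph is unmodified.
    ``r = 0`` returns an identical copy.

    Raises
    ------
    ValueError
        If ``r >= 1`` (could produce non-positive costs) or ``r < 0``.
    """
    if not (0 <= r < 1):
        raise ValueError(f"noise level r must lie in [0, 1), got {r}")
    if noise not in NOISE_MODELS:
        raise ValueError(f"unknown noise model {noise!r}")
    edges = sorted(canonical_edge(u, v) for u, v in g.graph.edges)
    costs = np.array([g.cost(u, v) for u, v in edges])
    u = rng.uniform(-r, r, size=len(edges))
    if noise == "multiplicative":
        new = costs * (1.0 + u)
    else:
        mean = float(costs.mean()) if len(costs) else 0.0
        new = np.maximum(costs + u * mean, np.finfo(float).tiny)
    return g.reweighted(dict(zip(edges, new.tolist())))


def pcsf_rand(
    g: PrizedInteractome,
    params: SolverParams,
    cfg: RandConfig,
) -> RobustForest:
    """Solve the PCSF on ``cfg.n`` independently perturbed graphs and
    combine the solutions into a :class:`RobustForest`.

    Solver errors are annotated with the index of the failing run.
    """
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n)
    runs: list[Forest] = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        try:
            noisy = perturb_costs(g, cfg.r, rng, cfg.noise)
            runs.append(solve_pcsf(noisy, params))
        except Exception as exc:
            raise RuntimeError(f"randomized run {i} of {cfg.n} failed: {exc}") from exc

    node_count: dict[str, int] = {}
    edge_count: dict[tuple[str, str], int] = {}
    for f in runs:
        for v in f.nodes:
            node_count[v] = node_count.get(v, 0) + 1
        for e in f.edges:
            edge_count[e] = edge_count.get(e, 0) + 1
    return RobustForest(
        n_runs=cfg.n,
        union_nodes=frozenset(node_count),
        union_edges=frozenset(edge_count),
        node_count=tuple(sorted(node_count.items())),
        edge_count=tuple(sorted(edge_count.items())),
        runs=tuple(runs),
    )
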