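import random

import pytest
from hypothesis import HealthCheck, settings

from pcsf import SolverParams, assign_prizes, construct_interactome
from pcsf.synthgen import (
    hub_prizes,
    hub_rows,
    toy1_prizes,
    toy1_rows,
    two_cluster_prizes,
    two_cluster_rows,
)

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def random_instance(rng: random.Random, max_nodes: int = 10, max_edges: int = 14):
    """A small random prized instance for oracle comparisons: random costs
    in (0.05, 1], random prizes in (0.1, 4], w drawn from {0.5, 1, 2}."""
    n = rng.randint(4, max_nodes)
    max_m = min(max_edges, n * (n - 1) // 2)
    m = rng.randint(max(1, n - 2), max_m)
    nodes = [f"n{i}" for i in range(n)]
    pairs = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]]
    rng.shuffle(pairs)
    rows = [(a, b, round(rng.uniform(0.05, 1.0), 3)) for a, b in pairs[:m]]
    g = construct_interactome(rows)
    n_term = rng.randint(1, max(1, n // 2))
    prizes = {
        v: round(rng.uniform(0.1, 4.0), 3)
        for v in rng.sample(sorted(g.nodes), n_term)
    }
    w = rng.choice([0.5, 1, 2])
    params = SolverParams(beta=1.0, w=w, mu=0.0)
    return assign_prizes(g, prizes, params), params


@pytest.fixture
def toy1():
    params = SolverParams(beta=1.0, w=2.0, mu=0.0)
    g = construct_interactome(toy1_rows())
    return assign_prizes(g, toy1_prizes(), params), params


@pytest.fixture
def two_cluster():
    def make(w: float):
        params = SolverParams(beta=1.0, w=w, mu=0.0)
        g = construct_interactome(two_cluster_rows())
        return assign_prizes(g, two_cluster_prizes(), params), params

    return make


@pytest.fixture
def hub():
    def make(mu: float):
        params = SolverParams(beta=1.0, w=2.0, mu=mu)
        g = construct_interactome(hub_rows())
        return assign_prizes(g, hub_prizes(), params), params

    return make
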