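import dataclasses

import numpy as np
import pytest

from netprop import (
    GeneNetwork,
    MINI_PRESET,
    ScenarioConfig,
    generate_scenario,
    normalize_adjacency,
)


@pytest.fixture
def single_edge_op():
    """Two genes joined by one unit edge: S = [[0,1],[1,0]]."""
    return normalize_adjacency(GeneNetwork.from_edges([("A", "B")]))


@pytest.fixture
def path_net():
    """Path A-B-C with unit weights."""
    return GeneNetwork.from_edges([("A", "B"), ("B", "C")])


@pytest.fixture(scope="session")
def mini_bundle():
    """Small high-signal scenario shared by smoke tests."""
    cfg = dataclasses.replace(MINI_PRESET, seed=11)
    net, pathways, cohort, clinical, truth = generate_scenario(cfg)
    return {
        "cfg": cfg,
        "net": net,
        "pathways": pathways,
        "cohort": cohort,
        "clinical": clinical,
        "truth": truth,
        "op": normalize_adjacency(net),
    }


@pytest.fixture(scope="session")
def default_bundle():
    """One default-condition scenario (120 patients, 3 subgroups)."""
    cfg = ScenarioConfig(seed=5)
    net, pathways, cohort, clinical, truth = generate_scenario(cfg)
    return {
        "cfg": cfg,
        "net": net,
        "pathways": pathways,
        "cohort": cohort,
        "clinical": clinical,
        "truth": truth,
        "op": normalize_adjacency(net),
    }


def random_network(rng: np.random.Generator, max_nodes: int = 100) -> GeneNetwork:
    """Erdos-Renyi-ish random graph helper for oracle-equivalence tests."""
    n = int(rng.integers(2, max_nodes + 1))
    p = float(rng.uniform(0.02, 0.3))
    genes = [f"N{i:03d}" for i in range(n)]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.append((genes[i], genes[j], float(rng.uniform(0.1, 2.0))))
    return GeneNetwork.from_edges(edges, extra_nodes=genes)
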