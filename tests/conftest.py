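import numpy as np
import pandas as pd
import pytest

from fercerna import (
    ExpressionMatrix,
    SimulationConfig,
    analyze_dataset,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def default_dataset():
    """One simulated study at the default (strong-effect) conditions."""
    return simulate_dataset(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def default_analysis(default_dataset):
    """Full pipeline result on the default simulated study."""
    return analyze_dataset(default_dataset)


@pytest.fixture
def toy_matrix():
    """3 vs 3 matrix with one clear up gene, one null gene, one flat gene."""
    values = pd.DataFrame(
        {
            "c1": [10.0, 5.0, 7.0],
            "c2": [10.5, 5.2, 7.0],
            "c3": [9.8, 4.9, 7.0],
            "n1": [6.0, 5.1, 7.0],
            "n2": [6.3, 5.0, 7.0],
            "n3": [5.9, 5.05, 7.0],
        },
        index=["UPGENE", "NULLGENE", "FLATGENE"],
    )
    groups = pd.Series(
        {"c1": "case", "c2": "case", "c3": "case",
         "n1": "control", "n2": "control", "n3": "control"}
    )
    return ExpressionMatrix(values=values, groups=groups, rna_class="mRNA")


def random_graph(rng: np.random.Generator, max_nodes: int = 12):
    """Small Erdos-Renyi-style graph for brute-force centrality oracles."""
    import networkx as nx

    n = int(rng.integers(3, max_nodes + 1))
    p = float(rng.uniform(0.15, 0.6))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(i, j)
    return g
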