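import numpy as np
import pytest

from argwalker import Scenario, load_arg, simulate_sample


@pytest.fixture(scope="session")
def six_node_graph():
    """The worked recombination example: two roots, one recombination node."""
    return load_arg(
        [(0, 2), (1, 2), (2, 3), (2, 4), (0, 5)],
        {3: "x", 4: "y", 5: "z"},
    )


@pytest.fixture(scope="session")
def default_sample():
    """One two-allele sample under the standard study conditions."""
    return simulate_sample(Scenario(seed=421, tag="fixture"))


def random_dag(rng: np.random.Generator, n_max: int, *, p_edge: float = 0.25):
    """A random sparse DAG with every sink labelled (no lost walk mass)."""
    n = int(rng.integers(2, n_max + 1))
    order = rng.permutation(n)
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                edges.append((int(order[i]), int(order[j])))
    if not edges:
        edges = [(int(order[0]), int(order[1]))]
    heads = {u for u, _ in edges}
    sinks = sorted({v for _, v in edges} - heads)
    labels = {s: f"h{s}" for s in sinks}
    return load_arg(edges, labels)
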