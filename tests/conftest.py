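import numpy as np
import pytest

from profclust import BenchmarkSpec, InternalBackend, simulate_superfamily


def random_binary_newick(n_leaves: int, rng: np.random.Generator) -> str:
    """Random rooted binary tree over n_leaves labelled tips with random
    branch lengths."""
    nodes = [f"L{i}" for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        la, lb = rng.uniform(0.05, 2.0, size=2)
        merged = f"({a}:{la:.4f},{b}:{lb:.4f})"
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)]
        nodes.append(merged)
    return nodes[0] + ";"


@pytest.fixture(scope="session")
def engine():
    return InternalBackend()


@pytest.fixture(scope="session")
def small_benchmark():
    """3 well-separated families, 6 training + 8 targets each."""
    return simulate_superfamily(
        BenchmarkSpec(
            n_families=3, n_train=6, n_target=8, length=120,
            within=0.2, between=1.2, seed=11,
        )
    )
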