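import numpy as np
import pytest

import moranet as mn


def random_connected_graph(n: int, rng: np.random.Generator) -> mn.WeightedGraph:
    """Connected Erdos-Renyi graph with edge probability 2 ln n / n."""
    p = min(1.0, 2.0 * np.log(n) / n)
    return mn.make_erdos_renyi(n, p, int(rng.integers(0, 2**31 - 1)))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture(scope="session")
def small_graph_corpus(rng):
    """A spread of small structures used by several property tests."""
    return [
        mn.make_complete(4),
        mn.make_complete(8),
        mn.make_star(6),
        mn.make_cycle(7),
        mn.make_complete_bipartite(5, 3),
        mn.make_complete_bipartite(6, 2, 3.0),
        mn.make_random_tree(8, 11),
        mn.make_erdos_renyi(8, 0.45, 5),
        mn.make_star_plus_edges(8, 3, 2),
    ]
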