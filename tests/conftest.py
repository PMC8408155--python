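import networkx as nx
import numpy as np
import pytest

from gdismantle.model import ModelConfig, build_model
from gdismantle.netgen import build_forced_corpus, make_bridged_cliques


def naive_optimal_sets(g, target_fraction):
    """Independent brute-force oracle built on networkx only.

    Enumerates subsets with itertools and measures components with
    networkx; no shared code with the package's bitmask enumeration.
    """
    import math
    from itertools import combinations

    n = g.number_of_nodes()
    t = math.ceil(target_fraction * n)

    def lcc_after(subset):
        h = g.copy()
        h.remove_nodes_from(subset)
        if h.number_of_nodes() == 0:
            return 0
        return max(len(c) for c in nx.connected_components(h))

    if lcc_after(()) <= t:
        return t, 0, [()]
    nodes = sorted(g.nodes)
    for k in range(1, n + 1):
        found = [s for s in combinations(nodes, k) if lcc_after(s) <= t]
        if found:
            return t, k, found
    raise AssertionError("unreachable")


@pytest.fixture(scope="session")
def tiny_model():
    """A small trained scorer that reliably top-ranks forced optima
    (star hubs and clique bridges); cheap enough for unit tests."""
    corpus = build_forced_corpus(150, seed=11)
    model = build_model(
        ModelConfig(
            conv_channels=(20, 10),
            attention_heads=(5, 5),
            regressor_widths=(30,),
            epochs=30,
            seed=3,
        )
    )
    return model.fit(corpus)


@pytest.fixture
def two_clique_bridge_toy():
    """Two 12-cliques joined through one bridge node (node 24; 25 nodes,
    matching the scale of the training family)."""
    return make_bridged_cliques(12, 12, n_bridges=1)


def random_small_graph(rng, n_max=12):
    n = int(rng.integers(5, n_max + 1))
    kind = rng.integers(0, 3)
    seed = int(rng.integers(0, 2**31 - 1))
    if kind == 0:
        return nx.gnp_random_graph(n, float(rng.uniform(0.15, 0.5)), seed=seed)
    if kind == 1:
        return nx.barabasi_albert_graph(n, int(rng.integers(1, 3)), seed=seed)
    return nx.random_regular_graph(2, n, seed=seed)  # cycle-like
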