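import math

import networkx as nx
import numpy as np
import pytest

from gdismantle.netgen import (
    OptimalSolutionSet,
    brute_force_optimal_sets,
    build_forced_corpus,
    build_training_corpus,
    compute_labels,
    generate_network,
    load_corpus,
    save_corpus,
)
from conftest import naive_optimal_sets, random_small_graph


@pytest.mark.parametrize(
    "model,params",
    [
        ("erdos_renyi", {"p": 0.2}),
        ("barabasi_albert", {"m": 2}),
        ("static_power_law", {"exponent": 2.5, "m_edges": 40}),
    ],
)
def test_generators_are_simple_deterministic_and_sized(model, params):
    g1 = generate_network(model, 25, params, seed=7)
    g2 = generate_network(model, 25, params, seed=7)
    assert g1.number_of_nodes() == 25
    assert sorted(g1.edges()) == sorted(g2.edges())
    assert not any(u == v for u, v in g1.edges())
    assert max((d for _, d in g1.degree), default=0) <= 24
    g3 = generate_network(model, 25, params, seed=8)
    assert sorted(g3.edges()) != sorted(g1.edges())  # seed actually matters


def test_barabasi_albert_growth_is_connected():
    g = generate_network("barabasi_albert", 25, {"m": 2}, seed=1)
    assert nx.is_connected(g)


@pytest.mark.parametrize(
    "model,params,err",
    [
        ("no_such_model", {}, "unknown generator"),
        ("erdos_renyi", {"p": 1.5}, "probability"),
        ("barabasi_albert", {"m": 0}, "m must be"),
        ("static_power_law", {"exponent": 0.5, "m_edges": 10}, "exponent"),
    ],
)
def test_generator_parameter_validation(model, params, err):
    with pytest.raises(ValueError, match=err):
        generate_network(model, 25, params, seed=0)


def test_brute_force_path_star_and_cycle():
    # path 0-1-2-3-4, LCC target 2: only the middle node splits it
    sols = brute_force_optimal_sets(nx.path_graph(5), 0.4)
    assert (sols.target_size, sols.k, sols.sets) == (2, 1, ((2,),))
    # star: hub removal isolates all leaves
    sols = brute_force_optimal_sets(nx.star_graph(4), 0.2)
    assert (sols.k, sols.sets) == (1, ((0,),))
    # 6-cycle, target 3: all 9 vertex pairs at cycle distance 2 or 3
    sols = brute_force_optimal_sets(nx.cycle_graph(6), 0.5)
    assert sols.k == 2 and len(sols.sets) == 9
    dist = dict(nx.all_pairs_shortest_path_length(nx.cycle_graph(6)))
    assert all(dist[a][b] in (2, 3) for a, b in sols.sets)


def test_brute_force_trivially_satisfied_graph_returns_empty_set():
    g = nx.Graph()
    g.add_edges_from([(0, 1), (2, 3)])
    g.add_node(4)
    sols = brute_force_optimal_sets(g, 0.5)  # t=3 >= LCC already
    assert (sols.k, sols.sets) == (0, ((),))


def test_brute_force_guards():
    with pytest.raises(ValueError, match="safety cap"):
        brute_force_optimal_sets(nx.path_graph(31), 0.18)
    with pytest.raises(ValueError, match="target_fraction"):
        brute_force_optimal_sets(nx.path_graph(5), 1.2)


def test_brute_force_matches_independent_oracle():
    rng = np.random.default_rng(5)
    for _ in range(15):
        g = random_small_graph(rng, n_max=9)
        t, k, sets = naive_optimal_sets(g, 0.25)
        sols = brute_force_optimal_sets(g, 0.25)
        assert (sols.target_size, sols.k) == (t, k)
        assert sorted(sols.sets) == sorted(tuple(s) for s in sets)


def test_enumeration_is_order_independent_under_relabeling():
    g = nx.barabasi_albert_graph(9, 2, seed=4)
    sols = brute_force_optimal_sets(g, 0.25)
    perm = {v: (v * 5 + 3) % 9 for v in g.nodes}
    sols_p = brute_force_optimal_sets(nx.relabel_nodes(g, perm), 0.25)
    expected = sorted(tuple(sorted(perm[v] for v in s)) for s in sols.sets)
    assert sorted(sols_p.sets) == expected


def test_labels_worked_examples():
    # single optimal set: members 1, everyone else 0
    sols = brute_force_optimal_sets(nx.star_graph(4), 0.2)
    assert compute_labels(sols) == {0: 1.0, 1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0}
    # kite (hub 3 + leaves 0,1,2, extra edge 0-1), target LCC<=1:
    # exactly two optimal sets {3,0} and {3,1}
    kite = nx.Graph([(3, 0), (3, 1), (3, 2), (0, 1)])
    sols = brute_force_optimal_sets(kite, 0.25)
    assert sols.sets == ((0, 3), (1, 3))
    assert compute_labels(sols) == {3: 1.0, 0: 0.5, 1: 0.5, 2: 0.0}
    # 6-cycle: every node is in 3 of the 9 sets
    sols = brute_force_optimal_sets(nx.cycle_graph(6), 0.5)
    labels = compute_labels(sols)
    assert all(abs(l - 1 / 3) < 1e-15 for l in labels.values())
    assert abs(math.fsum(labels.values()) - sols.k) < 1e-12


def test_labels_empty_solution_list_rejected():
    sols = OptimalSolutionSet(2, 1, (), (0, 1, 2), "x")
    with pytest.raises(ValueError):
        compute_labels(sols)


def test_label_sum_equals_k_on_random_graphs():
    rng = np.random.default_rng(17)
    for _ in range(10):
        g = random_small_graph(rng)
        sols = brute_force_optimal_sets(g, 0.25)
        labels = compute_labels(sols)
        assert abs(math.fsum(labels.values()) - sols.k) < 1e-12
        assert all(0.0 <= l <= 1.0 for l in labels.values())


def test_every_optimal_set_meets_target_when_rechecked_with_networkx():
    rng = np.random.default_rng(23)
    for _ in range(8):
        g = random_small_graph(rng)
        sols = brute_force_optimal_sets(g, 0.3)
        for s in sols.sets:
            h = g.copy()
            h.remove_nodes_from(s)
            lcc = max((len(c) for c in nx.connected_components(h)), default=0)
            assert lcc <= sols.target_size


def test_corpus_is_deterministic_and_label_sums_match_k():
    kwargs = dict(n_networks=6, n_nodes=12, seed=0, target_fraction=0.25)
    c1 = build_training_corpus(**kwargs)
    c2 = build_training_corpus(**kwargs)
    assert len(c1) == 6
    for s1, s2 in zip(c1, c2):
        assert sorted(s1.graph.edges()) == sorted(s2.graph.edges())
        assert s1.labels == s2.labels
        assert s1.provenance["generator"] in (
            "barabasi_albert", "erdos_renyi", "static_power_law"
        )
        assert abs(math.fsum(s1.labels.values()) - s1.provenance["k"]) < 1e-12
        assert len(s1.labels) == 12


def test_corpus_rejects_zero_networks():
    with pytest.raises(ValueError):
        build_training_corpus(0)


def test_forced_corpus_has_unique_single_node_optima():
    corpus = build_forced_corpus(8, seed=2)
    for s in corpus:
        assert s.provenance["k"] == 1
        opt = s.provenance["optimal_node"]
        assert s.labels[opt] == 1.0
        assert sum(v == 1.0 for v in s.labels.values()) == 1


def test_corpus_serialization_roundtrip(tmp_path):
    corpus = build_training_corpus(3, n_nodes=10, seed=1, target_fraction=0.3)
    save_corpus(corpus, tmp_path / "c")
    loaded = load_corpus(tmp_path / "c")
    assert len(loaded) == 3
    for a, b in zip(corpus, loaded):
        assert sorted(a.graph.nodes) == sorted(b.graph.nodes)
        assert sorted(map(tuple, map(sorted, a.graph.edges()))) == sorted(
            map(tuple, map(sorted, b.graph.edges()))
        )
        assert a.labels == pytest.approx(b.labels)
        assert b.provenance["generator"] == a.provenance["generator"]
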