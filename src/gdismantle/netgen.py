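"""Synthetic training networks and brute-force optimal dismantling sets.

Training data for the node-scoring model are small synthetic graphs
(Barabási–Albert, Erdős–Rényi, and static power-law; 25 nodes by default)
dismantled *optimally* by exhaustive enumeration: the minimum number k of
node removals that brings the largest connected component (LCC) at or
below a target size, together with *all* size-k sets achieving it.  Each
node's training label is the fraction of optimal sets it belongs to.
"""

from __future__ import annotations

import math
import random as _random
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

GENERATORS = ("barabasi_albert", "erdos_renyi", "static_power_law")

#: Default LCC target for optimal dismantling, as a fraction of N.
DEFAULT_TARGET_FRACTION = 0.18

#: Safety cap on N for exhaustive enumeration.
DEFAULT_MAX_NODES = 30


@dataclass(frozen=True)
class OptimalSolutionSet:
    """All minimum-cardinality node sets that meet the LCC target.

    Attributes
    ----------
    target_size : int
        LCC ceiling ``t``; every solution leaves ``LCC <= t``.
    k : int
        Minimum removal-set cardinality (0 if the graph already meets the
        target; then ``sets`` holds the single empty set).
    sets : tuple of tuple of int
        All size-``k`` solutions, each sorted, the list itself in
        lexicographic order.
    nodes : tuple of int
        Node ids of the source graph (sorted).
    graph_ref : str
        Identifier of the source graph (free-form provenance).
    """

    target_size: int
    k: int
    sets: tuple
    nodes: tuple
    graph_ref: str = ""


@dataclass
class TrainingSample:
    """One labeled synthetic network.

    ``labels`` maps node id -> rate in [0, 1] (fraction of optimal sets
    containing the node); label values sum to k over the whole graph.
    ``features`` is filled by :func:`gdismantle.features.compute_node_features`
    (a DataFrame indexed by node id) and may be ``None`` until then.
    """

    graph: nx.Graph
    labels: dict
    features: object = None
    provenance: dict = field(default_factory=dict)


def generate_network(model_name: str, n: int, params: Mapping, seed: int) -> nx.Graph:
    """Generate a simple undirected synthetic network.

    Parameters
    ----------
    model_name : {"barabasi_albert", "erdos_renyi", "static_power_law"}
    n : int
        Number of nodes (>= 2).
    params : mapping
        Generator parameters: ``m`` (BA edges per new node), ``p`` (ER edge
        probability), ``exponent`` and ``m_edges`` (static power-law degree
        exponent and edge count).
    seed : int
        Seed; identical (model, n, params, seed) yields an identical graph.
    """
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    if model_name == "barabasi_albert":
        m = int(params["m"])
        if not 1 <= m < n:
            raise ValueError(f"BA parameter m must be in [1, n), got {m}")
        g = nx.barabasi_albert_graph(n, m, seed=seed)
    elif model_name == "erdos_renyi":
        p = float(params["p"])
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"ER probability must be in [0, 1], got {p}")
        g = nx.gnp_random_graph(n, p, seed=seed)
    elif model_name == "static_power_law":
        g = _static_power_law(n, params, seed)
    else:
        raise ValueError(f"unknown generator {model_name!r}; expected one of {GENERATORS}")
    return g


def _static_power_law(n: int, params: Mapping, seed: int) -> nx.Graph:
    """Static power-law model (Goh et al.): igraph's generator, seeded."""
    import igraph

    exponent = float(params.get("exponent", 2.5))
    if exponent <= 1.0:
        raise ValueError(f"power-law exponent must exceed 1, got {exponent}")
    m_edges = int(params.get("m_edges", 2 * n))
    max_edges = n * (n - 1) // 2
    if not 0 <= m_edges <= max_edges:
        raise ValueError(f"edge count {m_edges} outside [0, {max_edges}]")
    # igraph draws from a caller-injectable Python RNG; swap it in and restore.
    rng = _random.Random(seed)
    igraph.set_random_number_generator(rng)
    try:
        ig = igraph.Graph.Static_Power_Law(n, m_edges, exponent_out=exponent)
    finally:
        igraph.set_random_number_generator(_random)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(ig.get_edgelist())
    g.remove_edges_from(nx.selfloop_edges(g))
    return g


def _lcc_at_most(adj: Sequence[int], alive: int, t: int) -> bool:
    """True iff every connected component of the bitmask-induced subgraph
    has at most ``t`` nodes.  Early-exits as soon as one component exceeds t.

    ``adj[i]`` is the neighbor bitmask of node-slot i; ``alive`` masks the
    present slots.
    """
    remaining = alive
    while remaining:
        start = remaining & -remaining
        seen = start
        frontier = start
        while frontier:
            nxt = 0
            f = frontier
            while f:
                b = f & -f
                f ^= b
                nxt |= adj[b.bit_length() - 1]
            frontier = nxt & alive & ~seen
            seen |= frontier
            if seen.bit_count() > t:
                return False
        remaining &= ~seen
    return True


def brute_force_optimal_sets(
    g: nx.Graph,
    target_fraction: float = DEFAULT_TARGET_FRACTION,
    max_nodes: int = DEFAULT_MAX_NODES,
    graph_ref: str = "",
) -> OptimalSolutionSet:
    """Enumerate all minimum node sets whose removal meets the LCC target.

    The target is ``t = ceil(target_fraction * N)``.  Subsets are tried in
    lexicographic order of sorted node ids, by increasing cardinality; at
    the first cardinality k with at least one solution, *all* size-k
    solutions are returned.  If the graph already satisfies ``LCC <= t``
    the result is ``k = 0`` with the single empty set.

    Only nodes lying in components larger than t need be considered: a
    minimum solution can never contain a node of an already-small
    component (dropping it would give a smaller solution).
    """
    if not 0.0 < target_fraction < 1.0:
        raise ValueError(f"target_fraction must be in (0, 1), got {target_fraction}")
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    if n > max_nodes:
        raise ValueError(
            f"N={n} exceeds the enumeration safety cap {max_nodes}; "
            "raise max_nodes explicitly if you really mean it"
        )
    t = math.ceil(target_fraction * n)
    nodes = tuple(sorted(g.nodes))
    slot = {v: i for i, v in enumerate(nodes)}
    adj = [0] * n
    for u, v in g.edges():
        if u == v:
            continue
        adj[slot[u]] |= 1 << slot[v]
        adj[slot[v]] |= 1 << slot[u]
    full = (1 << n) - 1

    if _lcc_at_most(adj, full, t):
        return OptimalSolutionSet(t, 0, ((),), nodes, graph_ref)

    # Candidate nodes: members of components larger than t.
    candidates = [
        v for comp in nx.connected_components(g) if len(comp) > t for v in comp
    ]
    candidates.sort()

    for k in range(1, len(candidates) + 1):
        found = []
        for subset in combinations(candidates, k):
            removed = 0
            for v in subset:
                removed |= 1 << slot[v]
            if _lcc_at_most(adj, full & ~removed, t):
                found.append(subset)
        if found:
            return OptimalSolutionSet(t, k, tuple(found), nodes, graph_ref)
    raise RuntimeError("unreachable: removing all candidate nodes meets any target")


def compute_labels(solutions: OptimalSolutionSet) -> dict:
    """Training labels: membership count over optimal sets / number of sets.

    Nodes in every optimal set get 1, nodes in none get 0; the label sum
    over all nodes equals k.
    """
    if not solutions.sets:
        raise ValueError("solution list is empty")
    n_sets = len(solutions.sets)
    counts = {v: 0 for v in solutions.nodes}
    for s in solutions.sets:
        for v in s:
            counts[v] += 1
    return {v: c / n_sets for v, c in counts.items()}


DEFAULT_GENERATOR_MIX = {"barabasi_albert": 1.0, "erdos_renyi": 1.0, "static_power_law": 1.0}

#: Per-generator parameter ranges the corpus builder samples from.
DEFAULT_PARAM_RANGES = {
    "barabasi_albert": {"m": (1, 3)},            # uniform integer
    "erdos_renyi": {"p": (0.08, 0.25)},          # uniform real
    "static_power_law": {"exponent": (2.0, 3.0), "m_edges_per_node": (1.0, 2.0)},
}


def build_training_corpus(
    n_networks: int,
    n_nodes: int = 25,
    generator_mix: Mapping | None = None,
    target_fraction: float = DEFAULT_TARGET_FRACTION,
    seed: int = 0,
    param_ranges: Mapping | None = None,
    feature_names: Sequence | None = ("degree", "chi2", "clustering", "kcore"),
) -> list:
    """Generate, optimally dismantle, and label a corpus of small networks.

    Deterministic under a fixed seed.  Each sample records its generator,
    parameters, and per-network seed in ``provenance``; features for
    ``feature_names`` are attached (pass ``None`` to skip).
    """
    if n_networks < 1:
        raise ValueError(f"need n_networks >= 1, got {n_networks}")
    mix = dict(generator_mix or DEFAULT_GENERATOR_MIX)
    unknown = set(mix) - set(GENERATORS)
    if unknown:
        raise ValueError(f"unknown generators in mix: {sorted(unknown)}")
    ranges = {**DEFAULT_PARAM_RANGES, **(param_ranges or {})}
    names = [m for m in GENERATORS if mix.get(m, 0) > 0]
    weights = np.array([mix[m] for m in names], dtype=float)
    weights /= weights.sum()

    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n_networks):
        model_name = names[rng.choice(len(names), p=weights)]
        params = _draw_params(model_name, n_nodes, ranges[model_name], rng)
        net_seed = int(rng.integers(0, 2**31 - 1))
        g = generate_network(model_name, n_nodes, params, net_seed)
        sols = brute_force_optimal_sets(g, target_fraction, graph_ref=f"corpus[{i}]")
        labels = compute_labels(sols)
        sample = TrainingSample(
            graph=g,
            labels=labels,
            provenance={
                "index": i,
                "generator": model_name,
                "params": params,
                "seed": net_seed,
                "k": sols.k,
                "t": sols.target_size,
                "n_optimal_sets": len(sols.sets),
            },
        )
        if feature_names is not None:
            from gdismantle.features import compute_node_features

            sample.features = compute_node_features(g, feature_names)
        samples.append(sample)
    return samples


def _draw_params(model_name: str, n_nodes: int, ranges: Mapping, rng) -> dict:
    if model_name == "barabasi_albert":
        lo, hi = ranges["m"]
        return {"m": int(rng.integers(lo, hi + 1))}
    if model_name == "erdos_renyi":
        lo, hi = ranges["p"]
        return {"p": float(rng.uniform(lo, hi))}
    lo, hi = ranges["exponent"]
    elo, ehi = ranges["m_edges_per_node"]
    return {
        "exponent": float(rng.uniform(lo, hi)),
        "m_edges": int(round(n_nodes * rng.uniform(elo, ehi))),
    }


def make_star(n_nodes: int = 25, hub: int = 0) -> nx.Graph:
    """Star: one hub adjacent to all other nodes."""
    g = nx.star_graph(n_nodes - 1)
    if hub != 0:
        g = nx.relabel_nodes(g, {0: hub, hub: 0})
    return g


def make_bridged_cliques(a: int, b: int, n_bridges: int = 1) -> nx.Graph:
    """Two cliques joined by parallel bridge nodes.

    Cliques on nodes 0..a-1 and a..a+b-1; ``n_bridges`` extra nodes each
    attach to two adjacent nodes of *each* clique (attachment points
    rotate around the cliques), so the network only splits once every
    bridge node is gone.  With a single bridge, that node is the unique
    one-node cut separating the cliques.
    """
    if min(a, b) < 2 or n_bridges < 1:
        raise ValueError("need cliques of >= 2 nodes and >= 1 bridge")
    g = nx.Graph()
    A = list(range(a))
    B = list(range(a, a + b))
    for grp in (A, B):
        g.add_edges_from((grp[i], grp[j]) for i in range(len(grp)) for j in range(i + 1, len(grp)))
    for i in range(n_bridges):
        v = a + b + i
        g.add_edges_from([(A[(2 * i) % a], v), (A[(2 * i + 1) % a], v)])
        g.add_edges_from([(v, B[(2 * i) % b]), (v, B[(2 * i + 1) % b])])
    return g


def build_forced_corpus(n_networks: int, n_nodes: int = 25, seed: int = 0) -> list:
    """Corpus of structurally forced single-node optima (stars and
    bridged clique pairs), brute-force labeled.

    These families have a unique minimum dismantling set of size one (the
    hub, resp. the bridge), which makes them a transparent recovery check
    for a trained scorer: ranking by p_n must put that node on top.  Node
    ids are randomly permuted per sample.  The LCC target is per family:
    the default ~18% for stars, and max clique size (just under 50%) for
    the bridged cliques, the tightest target their single cut node attains.
    """
    if n_networks < 1:
        raise ValueError(f"need n_networks >= 1, got {n_networks}")
    if n_nodes < 9:
        raise ValueError("forced families need at least 9 nodes")
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n_networks):
        perm = dict(enumerate(rng.permutation(n_nodes).tolist()))
        if i % 2 == 0:
            g = make_star(n_nodes)
            family, forced, tf = "star", perm[0], DEFAULT_TARGET_FRACTION
        else:
            half = (n_nodes - 1) // 2
            a = int(rng.integers(half - 1, half + 2))
            g = make_bridged_cliques(a, n_nodes - 1 - a)
            family, forced = "bridged_cliques", perm[n_nodes - 1]
            tf = (max(a, n_nodes - 1 - a) - 0.5) / n_nodes
        g = nx.relabel_nodes(g, perm)
        sols = brute_force_optimal_sets(g, tf, graph_ref=f"forced[{i}]")
        if sols.k != 1 or len(sols.sets) != 1 or sols.sets[0][0] != forced:
            raise RuntimeError(f"family construction broken at sample {i}")
        from gdismantle.features import compute_node_features

        samples.append(
            TrainingSample(
                graph=g,
                labels=compute_labels(sols),
                features=compute_node_features(g),
                provenance={
                    "index": i,
                    "generator": family,
                    "params": {"target_fraction": tf},
                    "seed": seed,
                    "k": 1,
                    "t": sols.target_size,
                    "optimal_node": forced,
                },
            )
        )
    return samples


# ---------------------------------------------------------------------------
# Corpus serialization: <i>.edges + <i>.labels per sample + flat manifest.


def save_corpus(samples: Sequence[TrainingSample], out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, s in enumerate(samples):
        with open(out / f"{i}.edges", "w") as fh:
            for u, v in sorted(tuple(sorted(e)) for e in s.graph.edges()):
                fh.write(f"{u} {v}\n")
            for v in sorted(nx.isolates(s.graph)):
                fh.write(f"# isolate {v}\n")
        with open(out / f"{i}.labels", "w") as fh:
            for v in sorted(s.labels):
                fh.write(f"{v} {s.labels[v]!r}\n")
        for key, val in s.provenance.items():
            if isinstance(val, dict):
                for pk, pv in val.items():
                    manifest.append(f"{i}.{key}.{pk}={pv}")
            else:
                manifest.append(f"{i}.{key}={val}")
    (out / "manifest.txt").write_text("\n".join(manifest) + "\n")


def load_corpus(in_dir) -> list:
    from pathlib import Path

    out = Path(in_dir)
    manifest = {}
    for line in (out / "manifest.txt").read_text().splitlines():
        if "=" in line:
            key, val = line.split("=", 1)
            manifest[key] = val
    samples = []
    i = 0
    while (out / f"{i}.edges").exists():
        g = nx.Graph()
        for line in (out / f"{i}.edges").read_text().splitlines():
            if line.startswith("# isolate"):
                g.add_node(int(line.split()[2]))
            elif line and not line.startswith("#"):
                u, v = line.split()[:2]
                g.add_edge(int(u), int(v))
        labels = {}
        for line in (out / f"{i}.labels").read_text().splitlines():
            v, lab = line.split()
            labels[int(v)] = float(lab)
        prov = {
            key.split(".", 1)[1]: val
            for key, val in manifest.items()
            if key.split(".", 1)[0] == str(i)
        }
        samples.append(TrainingSample(graph=g, labels=labels, provenance=prov))
        i += 1
    return samples
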