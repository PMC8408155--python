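"""Static attacks, the Simpson AUC robustness metric, greedy reinsertion,
and centrality-based baseline attacks.

An attack visits nodes in descending score order and removes each one
that still belongs to the largest connected component (LCC), until the
LCC falls to at most ``ceil(target_fraction * N)`` (default target: 10%
of the network).  Robustness is summarized by the area under the
LCC(x)/N curve over the removal index x, integrated with composite
Simpson's rule.  A greedy reinsertion pass then restores removed nodes
whose absence is not needed to hold the target, smallest resulting
component first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

HEURISTICS = ("degree", "betweenness", "inverse_degree", "inverse_betweenness")


@dataclass
class DismantlingTrace:
    """Record of one attack: removal order and per-step component sizes.

    ``lcc_sizes[i]`` / ``slcc_sizes[i]`` are the sizes of the largest and
    second-largest components *after* removing ``removal_list[i]``; the
    pre-attack sizes are ``initial_lcc`` / ``initial_slcc``.  ``auc`` is
    the Simpson integral of LCC(x)/n0 over x = 0..len(removal_list).
    """

    removal_list: list
    lcc_sizes: list
    slcc_sizes: list
    n0: int
    target_fraction: float
    initial_lcc: int
    initial_slcc: int
    auc: float = 0.0

    @property
    def target_size(self) -> int:
        return math.ceil(self.target_fraction * self.n0)

    def lcc_curve(self) -> list:
        """LCC fraction of n0 at removal counts 0, 1, ..., len(R)."""
        return [self.initial_lcc / self.n0] + [s / self.n0 for s in self.lcc_sizes]


def _component_sizes(g: nx.Graph):
    return sorted((len(c) for c in nx.connected_components(g)), reverse=True)


def lcc_slcc(g: nx.Graph):
    """Sizes of the largest and second-largest components (SLCC 0 if the
    graph has fewer than two components)."""
    sizes = _component_sizes(g)
    lcc = sizes[0] if sizes else 0
    slcc = sizes[1] if len(sizes) > 1 else 0
    return lcc, slcc


def _largest_components(g: nx.Graph):
    """Union of nodes over all components of maximal size (LCC membership
    under ties)."""
    comps = list(nx.connected_components(g))
    if not comps:
        return set()
    top = max(len(c) for c in comps)
    members = set()
    for c in comps:
        if len(c) == top:
            members |= c
    return members


def static_attack(g: nx.Graph, scores: Mapping, target_fraction: float = 0.10) -> DismantlingTrace:
    """Remove nodes in descending score order until the LCC target holds.

    Scores are computed once and never updated.  A visited node outside
    the current LCC is skipped (and not revisited); ties in score break
    by ascending node id.  Stops as soon as LCC <= ceil(target_fraction*N).
    """
    if not 0.0 < target_fraction < 1.0:
        raise ValueError(f"target_fraction must be in (0, 1), got {target_fraction}")
    missing = [v for v in g.nodes if v not in scores]
    if missing:
        raise ValueError(f"missing scores for nodes {sorted(missing)[:5]}...")
    n0 = g.number_of_nodes()
    t = math.ceil(target_fraction * n0)
    h = g.copy()
    initial_lcc, initial_slcc = lcc_slcc(h)
    order = sorted(g.nodes, key=lambda v: (-scores[v], v))
    removal, lccs, slccs = [], [], []
    lcc = initial_lcc
    # One pass normally suffices; further passes only trigger in the corner
    # case where a smaller component, skipped earlier, becomes the LCC.
    while lcc > t:
        progressed = False
        for v in order:
            if lcc <= t:
                break
            if v in h and v in _largest_components(h):
                h.remove_node(v)
                lcc, slcc = lcc_slcc(h)
                removal.append(v)
                lccs.append(lcc)
                slccs.append(slcc)
                progressed = True
        if not progressed:
            break
    trace = DismantlingTrace(removal, lccs, slccs, n0, target_fraction, initial_lcc, initial_slcc)
    trace.auc = dismantling_auc(trace.lcc_curve())
    return trace


def dismantling_auc(lcc_fractions: Sequence[float], normalize: bool = False) -> float:
    """Composite Simpson integral of the LCC curve over the removal index.

    Values are LCC(x)/N at unit-spaced removal counts x = 0..R.  An odd
    trailing interval is handled with the trapezoid rule; a single point
    spans a zero-width domain and integrates to 0.  ``normalize=True``
    divides by the domain width R.
    """
    vals = list(lcc_fractions)
    if not vals:
        raise ValueError("empty LCC curve")
    n = len(vals) - 1
    if n == 0:
        return 0.0
    auc = 0.0
    i = 0
    while i + 2 <= n:
        auc += (vals[i] + 4.0 * vals[i + 1] + vals[i + 2]) / 3.0
        i += 2
    if i < n:
        auc += (vals[i] + vals[i + 1]) / 2.0
    return auc / n if normalize else auc


def greedy_reinsertion(g: nx.Graph, trace: DismantlingTrace) -> DismantlingTrace:
    """Restore removed nodes whose removal is not needed for the target.

    Iteratively reinserts, among the removed nodes whose return (with all
    incident edges to present nodes) keeps LCC <= ceil(target_fraction*N),
    the one whose post-reinsertion component is smallest (ties: ascending
    node id), until no node qualifies.  The surviving removal set is a
    subset of the input's, still meets the target, and is maximal in the
    sense that no further single reinsertion is feasible.
    """
    unknown = [v for v in trace.removal_list if v not in g.nodes]
    if unknown:
        raise ValueError(f"removal list contains nodes absent from the graph: {unknown[:5]}")
    t = trace.target_size
    removed = set(trace.removal_list)
    present = set(g.nodes) - removed
    h = g.subgraph(present).copy()
    while True:
        comp_of = {}
        comp_sizes = []
        for ci, comp in enumerate(nx.connected_components(h)):
            comp_sizes.append(len(comp))
            for v in comp:
                comp_of[v] = ci
        lcc_now = max(comp_sizes, default=0)
        best = None
        for v in sorted(removed):
            touched = {comp_of[u] for u in g.neighbors(v) if u in comp_of}
            new_size = 1 + sum(comp_sizes[ci] for ci in touched)
            others = max(
                (s for ci, s in enumerate(comp_sizes) if ci not in touched), default=0
            )
            if max(new_size, others) <= t:
                if best is None or (new_size, v) < best[:2]:
                    best = (new_size, v)
        if best is None:
            break
        v = best[1]
        removed.discard(v)
        h.add_node(v)
        h.add_edges_from((v, u) for u in g.neighbors(v) if u in h)
    # Replay the surviving removals in their original order for the trace.
    new_order = [v for v in trace.removal_list if v in removed]
    return replay_attack(g, new_order, trace.target_fraction)


def replay_attack(g: nx.Graph, removal_list: Sequence, target_fraction: float) -> DismantlingTrace:
    """Trace (LCC/SLCC per step, AUC) for an explicit removal sequence."""
    h = g.copy()
    initial_lcc, initial_slcc = lcc_slcc(h)
    lccs, slccs = [], []
    for v in removal_list:
        h.remove_node(v)
        lcc, slcc = lcc_slcc(h)
        lccs.append(lcc)
        slccs.append(slcc)
    trace = DismantlingTrace(
        list(removal_list), lccs, slccs, g.number_of_nodes(), target_fraction,
        initial_lcc, initial_slcc,
    )
    trace.auc = dismantling_auc(trace.lcc_curve())
    return trace


def _centrality(g: nx.Graph, strategy: str) -> dict:
    base = strategy.removeprefix("inverse_")
    if base == "degree":
        c = dict(g.degree)
    elif base == "betweenness":
        c = nx.betweenness_centrality(g)
    else:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {HEURISTICS}")
    if strategy.startswith("inverse_"):
        c = {v: -x for v, x in c.items()}
    return c


def heuristic_attack(
    g: nx.Graph,
    strategy: str,
    target_fraction: float = 0.10,
    recompute: bool = False,
) -> DismantlingTrace:
    """Centrality-ranked attack (degree / betweenness and their inverses).

    ``inverse_*`` attacks remove low-centrality nodes first.  With
    ``recompute=True`` the centrality is re-evaluated on the damaged
    graph after every removal (a dynamic attack); otherwise the ranking
    is static, with the same LCC-membership skip rule and stop condition
    as :func:`static_attack`.
    """
    if strategy not in HEURISTICS:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {HEURISTICS}")
    if not recompute:
        return static_attack(g, _centrality(g, strategy), target_fraction)
    if not 0.0 < target_fraction < 1.0:
        raise ValueError(f"target_fraction must be in (0, 1), got {target_fraction}")
    n0 = g.number_of_nodes()
    t = math.ceil(target_fraction * n0)
    h = g.copy()
    initial_lcc, initial_slcc = lcc_slcc(h)
    removal, lccs, slccs = [], [], []
    lcc = initial_lcc
    while lcc > t:
        c = _centrality(h, strategy)
        members = _largest_components(h)
        v = min(members, key=lambda u: (-c[u], u))
        h.remove_node(v)
        lcc, slcc = lcc_slcc(h)
        removal.append(v)
        lccs.append(lcc)
        slccs.append(slcc)
    trace = DismantlingTrace(removal, lccs, slccs, n0, target_fraction, initial_lcc, initial_slcc)
    trace.auc = dismantling_auc(trace.lcc_curve())
    return trace
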