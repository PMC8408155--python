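"""Early-warning signal of systemic collapse and articulation-point traces.

The model's own virtual dismantling of a network defines how much damage
the system tolerates before percolating: Ω_m is the sum of the scores
p_n over S_o, the removed-node prefix up to the percolation point (the
first peak of the second-largest connected component, SLCC).  For an
arbitrary attack removing a set S, the early-warning value is

    Ω = min(Ω_s / Ω_m, 1),   Ω_s = Σ_{n in S} p_n,

a number in [0, 1] that approaches 1 quickly when structurally critical
nodes are being removed, well before the LCC size shows the collapse.
The first response time is the number of removals between the Ω = 0.5
crossing and the collapse (SLCC peak) — positive when the warning is
timely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from gdismantle.dismantle import DismantlingTrace, lcc_slcc, replay_attack, static_attack


@dataclass(frozen=True)
class OmegaBaseline:
    """Damage tolerance of a network under the model's own attack.

    ``s_o`` is the ordered prefix of the model-driven removal list up to
    and including the percolation point; ``omega_m`` the sum of the
    model scores over it.
    """

    s_o: tuple
    omega_m: float
    collapse_index: int
    scores: dict = field(default_factory=dict, compare=False)


@dataclass
class EarlyWarningTrace:
    """Per-removal early-warning series for one attack.

    ``pi[i]`` is the score of the node removed at step i (the attack
    intensity), ``omega_s`` the running score sum, ``omega`` the clipped
    ratio to the baseline, ``omega_prime`` its backward difference.
    ``collapse_index`` is the SLCC-peak step of this attack itself.
    """

    attack_sequence: list
    pi: list
    omega_s: list
    omega: list
    omega_prime: list
    lcc_sizes: list
    slcc_sizes: list
    collapse_index: int
    baseline: OmegaBaseline
    first_response_time: int | None = None


@dataclass
class APTrace:
    """Articulation points (APs) along a removal sequence.

    Entry i describes the graph *before* the i-th removal: ``n_ap[i]`` is
    the AP count and ``n_ap_in_r[i]`` how many of those APs still sit in
    the not-yet-removed tail of the removal list.  There are
    ``len(removal_list) + 1`` entries (the last one after all removals).
    """

    removal_list: list
    n_ap: list
    n_ap_in_r: list


def _slcc_peak_index(slcc_sizes: Sequence[int]) -> int:
    """Index of the first maximum of the SLCC series (percolation point)."""
    arr = np.asarray(slcc_sizes)
    return int(np.argmax(arr))


def compute_baseline(
    model,
    g: nx.Graph,
    target_fraction: float = 0.10,
    mode: str = "slcc_peak",
) -> OmegaBaseline:
    """Virtually dismantle ``g`` with the model and sum scores over S_o.

    ``mode="slcc_peak"`` (default) takes S_o as the removal prefix up to
    the first SLCC maximum — the percolation point; ``mode="target"``
    takes the full removal list down to the dismantling target.  The
    baseline uses the raw virtual dismantling, without reinsertion.
    """
    if g.number_of_nodes() < 3:
        raise ValueError("need at least 3 nodes for a defined SLCC peak")
    if mode not in ("slcc_peak", "target"):
        raise ValueError(f"unknown mode {mode!r}")
    scores = model if isinstance(model, Mapping) else model.predict_scores(g)
    trace = static_attack(g, scores, target_fraction)
    if not trace.removal_list:
        raise ValueError("graph already satisfies the dismantling target; no S_o")
    peak = _slcc_peak_index(trace.slcc_sizes)
    s_o = tuple(trace.removal_list) if mode == "target" else tuple(trace.removal_list[: peak + 1])
    omega_m = float(sum(scores[v] for v in s_o))
    return OmegaBaseline(s_o=s_o, omega_m=omega_m, collapse_index=peak, scores=dict(scores))


def omega_value(omega_s: float, omega_m: float) -> float:
    """Ω = Ω_s/Ω_m clipped at 1 (the system never warns beyond certainty)."""
    if omega_m <= 0:
        raise ValueError(f"omega_m must be positive, got {omega_m}")
    if omega_s < 0:
        raise ValueError(f"omega_s must be non-negative, got {omega_s}")
    return min(omega_s / omega_m, 1.0)


def omega_trace(
    model,
    g: nx.Graph,
    attack,
    baseline: OmegaBaseline | None = None,
    target_fraction: float = 0.10,
    warning_level: float = 0.5,
) -> EarlyWarningTrace:
    """Early-warning series along an attack.

    ``attack`` is a :class:`DismantlingTrace` or an explicit node
    sequence; ``model`` a fitted scorer or a precomputed {node: p_n}
    mapping.  The collapse index is the SLCC peak of the attack itself.
    """
    scores = model if isinstance(model, Mapping) else model.predict_scores(g)
    if baseline is None:
        baseline = compute_baseline(scores, g, target_fraction)
    if isinstance(attack, DismantlingTrace):
        seq = list(attack.removal_list)
        lccs, slccs = list(attack.lcc_sizes), list(attack.slcc_sizes)
    else:
        seq = list(attack)
        absent = [v for v in seq if v not in g.nodes]
        if absent:
            raise ValueError(f"attacked nodes absent from the graph: {absent[:5]}")
        rep = replay_attack(g, seq, target_fraction)
        lccs, slccs = rep.lcc_sizes, rep.slcc_sizes
    pi, om_s, om, om_p = [], [], [], []
    running = 0.0
    prev = 0.0
    for v in seq:
        p = float(scores[v])
        running += p
        w = omega_value(running, baseline.omega_m)
        pi.append(p)
        om_s.append(running)
        om.append(w)
        om_p.append(w - prev)
        prev = w
    collapse = _slcc_peak_index(slccs) if seq else 0
    trace = EarlyWarningTrace(
        attack_sequence=seq,
        pi=pi,
        omega_s=om_s,
        omega=om,
        omega_prime=om_p,
        lcc_sizes=lccs,
        slcc_sizes=slccs,
        collapse_index=collapse,
        baseline=baseline,
    )
    trace.first_response_time = first_response_time(trace, warning_level) if seq else None
    return trace


def first_response_time(trace: EarlyWarningTrace, warning_level: float = 0.5) -> int | None:
    """Removals between the Ω >= level crossing and the collapse.

    Positive means the warning preceded the collapse; ``None`` if the
    warning level is never reached.
    """
    if not 0.0 < warning_level <= 1.0:
        raise ValueError(f"warning_level must be in (0, 1], got {warning_level}")
    if not trace.omega:
        raise ValueError("empty early-warning trace")
    for i, w in enumerate(trace.omega):
        if w >= warning_level:
            return trace.collapse_index - i
    return None


def ap_trace(g: nx.Graph, removal_list: Sequence) -> APTrace:
    """Articulation points, removal after removal, along an attack.

    At each step the APs of the current graph are found via biconnected
    components, and the overlap with the not-yet-removed tail of the
    removal list is counted.
    """
    absent = [v for v in removal_list if v not in g.nodes]
    if absent:
        raise ValueError(f"removal list contains nodes absent from the graph: {absent[:5]}")
    h = g.copy()
    seq = list(removal_list)
    n_ap, n_in_r = [], []
    for i in range(len(seq) + 1):
        aps = set(nx.articulation_points(h))
        remaining = set(seq[i:])
        n_ap.append(len(aps))
        n_in_r.append(len(aps & remaining))
        if i < len(seq):
            h.remove_node(seq[i])
    return APTrace(removal_list=seq, n_ap=n_ap, n_ap_in_r=n_in_r)
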