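"""Per-node input features for the scoring model.

Four structural descriptors, chosen for their low computational cost:
degree (local), the chi-squared statistic of the degrees over a node's
neighborhood (local), the local clustering coefficient (second order) and
the k-core number (global).  Any caller-supplied per-node measure can be
used instead, e.g. to enhance an existing centrality-based heuristic by
feeding that centrality as the only feature.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

DEFAULT_FEATURES = ("degree", "chi2", "clustering", "kcore")


def neighborhood_chi2(g: nx.Graph) -> dict:
    """Chi-squared statistic of neighbor degrees around each node.

    For node v with neighbors Nb(v) and mean neighbor degree d̄:
    ``chi2(v) = sum_{u in Nb(v)} (deg(u) - d̄)^2 / d̄``; 0 for isolated
    nodes.  Measures how heterogeneous the degrees around v are — nodes
    bridging a hub and a periphery score high, nodes inside regular
    neighborhoods (e.g. cliques) score 0.
    """
    deg = dict(g.degree)
    out = {}
    for v in g.nodes:
        nbrs = list(g.neighbors(v))
        if not nbrs:
            out[v] = 0.0
            continue
        dbar = sum(deg[u] for u in nbrs) / len(nbrs)
        if dbar == 0:
            out[v] = 0.0
        else:
            out[v] = sum((deg[u] - dbar) ** 2 for u in nbrs) / dbar
    return out


def compute_node_features(
    g: nx.Graph,
    feature_names: Sequence = DEFAULT_FEATURES,
    custom_measures: Mapping | None = None,
    minmax: bool = False,
) -> pd.DataFrame:
    """Feature matrix, one row per node, columns in the requested order.

    ``feature_names`` entries are either the built-ins ``degree``,
    ``chi2``, ``clustering``, ``kcore``, or keys into ``custom_measures``
    (a mapping name -> {node: value}).  With ``minmax=True`` each column
    is rescaled to [0, 1] over this network (constant columns map to 0).
    """
    if not feature_names:
        raise ValueError("feature_names must be non-empty")
    custom = custom_measures or {}
    nodes = sorted(g.nodes)
    cols = {}
    for name in feature_names:
        if name in custom:
            vals = custom[name]
        elif name == "degree":
            vals = dict(g.degree)
        elif name == "chi2":
            vals = neighborhood_chi2(g)
        elif name == "clustering":
            vals = nx.clustering(g)
        elif name == "kcore":
            vals = nx.core_number(g)
        else:
            raise ValueError(f"unknown feature {name!r}")
        cols[name] = [float(vals[v]) for v in nodes]
    df = pd.DataFrame(cols, index=pd.Index(nodes, name="node"), columns=list(feature_names))
    if minmax:
        span = df.max() - df.min()
        span = span.replace(0.0, 1.0)
        df = (df - df.min()) / span
    return df


def features_to_tsv(features: pd.DataFrame, path) -> None:
    """Write a feature matrix as TSV with a header row (node + columns)."""
    features.to_csv(path, sep="\t")
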