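"""Edge-list reading and result writing.

Networks come in as whitespace-separated edge lists (two integer node
ids per line, extra columns ignored, ``#``/``%`` comment lines skipped);
they are always treated as simple undirected graphs, with duplicate
edges and self-loops dropped and logged.  Attack traces and
early-warning series go out as CSV with a flat key-value manifest so a
run can be reproduced from its output directory alone.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from gdismantle.dismantle import DismantlingTrace
from gdismantle.earlywarn import APTrace, EarlyWarningTrace

log = logging.getLogger("gdismantle")


def read_edge_list(path) -> nx.Graph:
    """Parse a whitespace-separated edge list into a simple graph.

    Node ids are the integers in the first two columns; further columns
    (e.g. weights) are ignored.  Lines starting with ``#`` or ``%`` and
    blank lines are skipped.  Duplicate edges, reversed duplicates and
    self-loops are dropped, with a single logged count per file.
    """
    path = Path(path)
    g = nx.Graph()
    dropped_dup = dropped_loop = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line[0] in "#%":
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least two columns")
            try:
                u, v = int(tokens[0]), int(tokens[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer node id") from exc
            if u == v:
                dropped_loop += 1
                g.add_node(u)
                continue
            if g.has_edge(u, v):
                dropped_dup += 1
                continue
            g.add_edge(u, v)
    if dropped_dup or dropped_loop:
        log.info(
            "%s: dropped %d duplicate edge(s) and %d self-loop(s); graph read as undirected simple",
            path, dropped_dup, dropped_loop,
        )
    return g


def trace_to_frame(trace: DismantlingTrace) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "removal_index": range(1, len(trace.removal_list) + 1),
            "node_id": trace.removal_list,
            "lcc_size": trace.lcc_sizes,
            "slcc_size": trace.slcc_sizes,
        }
    )


def earlywarning_to_frame(trace: EarlyWarningTrace) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "removal_index": range(1, len(trace.attack_sequence) + 1),
            "node_id": trace.attack_sequence,
            "pi": trace.pi,
            "omega_s": trace.omega_s,
            "omega": trace.omega,
            "omega_prime": trace.omega_prime,
            "lcc": trace.lcc_sizes,
            "slcc": trace.slcc_sizes,
        }
    )


def ap_trace_to_frame(trace: APTrace) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "removal_index": range(len(trace.n_ap)),
            "n_ap": trace.n_ap,
            "n_ap_in_r": trace.n_ap_in_r,
        }
    )


def _write_manifest(path: Path, entries: dict) -> None:
    lines = [f"{k}={v}" for k, v in entries.items()]
    path.write_text("\n".join(lines) + "\n")


def write_results(obj, out_dir, config: dict | None = None, overwrite: bool = False):
    """Write a trace object plus its manifest into ``out_dir``.

    Accepts a :class:`DismantlingTrace`, :class:`EarlyWarningTrace` or
    :class:`APTrace`.  Refuses an existing directory unless ``overwrite``
    is set.  Identical inputs reproduce identical files.
    """
    from gdismantle import __version__

    out = Path(out_dir)
    if out.exists() and not overwrite:
        raise FileExistsError(f"{out} exists; pass overwrite=True to replace it")
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"tool_version": __version__}
    manifest.update(config or {})
    if isinstance(obj, DismantlingTrace):
        trace_to_frame(obj).to_csv(out / "trace.csv", index=False)
        manifest.update(
            n0=obj.n0,
            target_fraction=obj.target_fraction,
            target_size=obj.target_size,
            n_removals=len(obj.removal_list),
            auc=repr(obj.auc),
        )
    elif isinstance(obj, EarlyWarningTrace):
        earlywarning_to_frame(obj).to_csv(out / "early_warning.csv", index=False)
        manifest.update(
            omega_m=repr(obj.baseline.omega_m),
            s_o_size=len(obj.baseline.s_o),
            collapse_index=obj.collapse_index,
            first_response_time=obj.first_response_time,
        )
    elif isinstance(obj, APTrace):
        ap_trace_to_frame(obj).to_csv(out / "ap_trace.csv", index=False)
        manifest.update(n_removals=len(obj.removal_list))
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    _write_manifest(out / "manifest.txt", manifest)
    return out


def read_config_file(path) -> dict:
    """Flat ``key=value`` config file; '#' comments and blanks skipped."""
    entries = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {line!r}")
        key, val = line.split("=", 1)
        entries[key.strip()] = val.strip()
    return entries
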