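"""Reading and writing the package's plain-text file formats.

Graph files are JSON:

    {"vertices": [...],
     "edges": [{"from": str, "to": str, "label": str}, ...],
     "parameters": {symbol: float},
     "input_symbol": str | null,
     "annotations": {vertex: [bits]}}          # optional

A TSV alternative carries three columns from/to/label (parameters go in a
JSON sidecar).  Partition files are {"blocks": [[v, ...], ...]}; mechanism
files follow the reaction-grammar schema (see :mod:`linfra.ptm`).
JSON round-trips are bit-exact: labels are serialised with sympy's
deterministic printer and key order is fixed.
"""

from __future__ import annotations

import json
from pathlib import Path

import sympy as sp

from .coarse import Partition
from .graph import LFGraph, build_graph
from .ptm import EnzymeMechanism, ModificationCycle, Reaction

__all__ = ["graph_to_dict", "graph_from_dict", "write_graph", "read_graph",
           "write_graph_tsv", "read_graph_tsv", "read_partition",
           "write_partition", "read_mechanism", "read_cycle"]


def _label_str(expr: sp.Expr) -> str:
    return sp.sstr(expr, order="lex")


def graph_to_dict(g: LFGraph) -> dict:
    d = {
        "vertices": list(g.vertices),
        "edges": [{"from": s, "to": t, "label": _label_str(g.edges[(s, t)])}
                  for (s, t) in sorted(g.edges)],
        "parameters": {k: float(g.parameters[k]) for k in sorted(g.parameters)},
        "input_symbol": g.input_symbol,
    }
    if g.annotations:
        d["annotations"] = {v: list(g.annotations[v]) for v in g.vertices
                            if v in g.annotations}
    return d


def graph_from_dict(d: dict) -> LFGraph:
    edges = [(e["from"], e["to"], e["label"]) for e in d["edges"]]
    ann = {k: tuple(v) for k, v in d.get("annotations", {}).items()}
    return build_graph(d["vertices"], edges, parameters=d.get("parameters"),
                       input_symbol=d.get("input_symbol"), annotations=ann)


def write_graph(g: LFGraph, path) -> None:
    Path(path).write_text(json.dumps(graph_to_dict(g), indent=1) + "\n")


def read_graph(path) -> LFGraph:
    return graph_from_dict(json.loads(Path(path).read_text()))


def write_graph_tsv(g: LFGraph, path, sidecar=None) -> None:
    lines = ["from\tto\tlabel"]
    for (s, t) in sorted(g.edges):
        lines.append(f"{s}\t{t}\t{_label_str(g.edges[(s, t)])}")
    Path(path).write_text("\n".join(lines) + "\n")
    if sidecar is not None:
        meta = {"vertices": list(g.vertices),
                "parameters": {k: g.parameters[k] for k in sorted(g.parameters)},
                "input_symbol": g.input_symbol}
        Path(sidecar).write_text(json.dumps(meta, indent=1) + "\n")


def read_graph_tsv(path, sidecar=None) -> LFGraph:
    lines = Path(path).read_text().strip().split("\n")
    rows = [ln.split("\t") for ln in lines[1:]]
    edges = [(r[0], r[1], r[2]) for r in rows]
    meta = json.loads(Path(sidecar).read_text()) if sidecar else {}
    vertices = meta.get("vertices")
    if vertices is None:
        vertices = []
        for (s, t, _) in edges:
            for v in (s, t):
                if v not in vertices:
                    vertices.append(v)
    return build_graph(vertices, edges, parameters=meta.get("parameters"),
                       input_symbol=meta.get("input_symbol"))


def read_partition(path) -> Partition:
    return Partition(json.loads(Path(path).read_text())["blocks"])


def write_partition(p: Partition, path) -> None:
    Path(path).write_text(json.dumps({"blocks": p.blocks}, indent=1) + "\n")


def mechanism_from_dict(d: dict) -> EnzymeMechanism:
    enzyme = d["enzyme"]
    reactions = []
    for r in d["reactions"]:
        kind = r["type"]
        if kind == "binding":
            rx = Reaction("binding", enzyme, r["to"], r["rate"], r["substrate"])
        elif kind == "conversion":
            rx = Reaction("conversion", r["from"], r["to"], r["rate"])
        else:
            rx = Reaction("release", r["from"], enzyme, r["rate"], r["substrate"])
        reactions.append(rx)
    return EnzymeMechanism(enzyme=enzyme, intermediates=d["intermediates"],
                           reactions=reactions,
                           parameters=d.get("parameters", {}))


def read_mechanism(path) -> EnzymeMechanism:
    return mechanism_from_dict(json.loads(Path(path).read_text()))


def read_cycle(path) -> ModificationCycle:
    d = json.loads(Path(path).read_text())
    return ModificationCycle(forward=mechanism_from_dict(d["forward"]),
                             reverse=mechanism_from_dict(d["reverse"]),
                             E_tot=d["E_tot"], F_tot=d["F_tot"],
                             S_tot=d["S_tot"])
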