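"""Labelled directed graphs and their Laplacian dynamics.

The central object is :class:`LFGraph`: a finite simple directed graph whose
edges carry positive rate labels (symbolic expressions over named parameters
and at most one designated input symbol).  The graph generates a linear
dynamics du/dt = L·u where L is the column-sum-zero Laplacian: each edge is
one-dimensional chemistry, moving material from its source vertex to its
target at the labelled rate.  Column sums of L vanish identically, so total
material is conserved.

Conventions (fixed, no variants offered):

* Laplacian is column-sum-zero with ``du/dt = L @ u``; ``L[j, i]`` holds the
  label of edge ``i -> j``.
* Vertex order is order of first declaration; every vector and matrix in the
  package uses it.  Identifiers are strings; integers are stringified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import sympy as sp
from scipy.integrate import solve_ivp

from .errors import (DuplicateEdge, GraphError, SelfLoop, UnknownVertex,
                     UnboundParameter)
from .labels import parse_label

__all__ = ["LFGraph", "build_graph", "laplacian", "numeric_laplacian",
           "is_strongly_connected", "is_reversible", "propagate"]


def _vname(v) -> str:
    return v if isinstance(v, str) else str(v)


@dataclass
class LFGraph:
    """Finite simple labelled directed graph.

    Attributes
    ----------
    vertices : list of str
        Ordered, distinct vertex identifiers.
    edges : dict
        Mapping ``(source, target) -> sympy label expression``.
    parameters : dict
        Optional mapping symbol name -> positive numeric value.
    input_symbol : str or None
        Name of the designated input symbol (ligand concentration), if any.
    annotations : dict
        Optional per-vertex metadata (e.g. binding bit-vectors on hypercube
        fixtures); not interpreted by this module.
    """

    vertices: list
    edges: dict
    parameters: dict = field(default_factory=dict)
    input_symbol: str | None = None
    annotations: dict = field(default_factory=dict)

    # -- basic views ------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.vertices)

    def index(self, v) -> int:
        return self._index[_vname(v)]

    def __post_init__(self):
        self._index = {v: i for i, v in enumerate(self.vertices)}

    def label(self, i, j) -> sp.Expr:
        return self.edges[(_vname(i), _vname(j))]

    def has_edge(self, i, j) -> bool:
        return (_vname(i), _vname(j)) in self.edges

    def successors(self, i) -> list:
        i = _vname(i)
        return [t for (s, t) in self.edges if s == i]

    def free_symbols(self) -> set:
        out = set()
        for expr in self.edges.values():
            out |= expr.free_symbols
        return out

    def substitutions(self, input_value=None) -> dict:
        """Parameter bindings as a sympy substitution map."""
        subs = {sp.Symbol(k): v for k, v in self.parameters.items()}
        if input_value is not None and self.input_symbol is not None:
            subs[sp.Symbol(self.input_symbol)] = input_value
        return subs

    def unbound_symbols(self, input_value=None) -> set:
        bound = set(self.substitutions(input_value))
        return {s for s in self.free_symbols() if s not in bound}

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.vertices)
        g.add_edges_from(self.edges)
        return g

    def with_parameters(self, **params) -> "LFGraph":
        new = dict(self.parameters)
        new.update(params)
        return LFGraph(list(self.vertices), dict(self.edges), new,
                       self.input_symbol, dict(self.annotations))

    def reversed_pairs(self) -> list:
        """Unordered reversible pairs (i, j) with both directions present."""
        seen = set()
        out = []
        for (i, j) in self.edges:
            if (j, i) in self.edges and (j, i) not in seen:
                seen.add((i, j))
                out.append((i, j))
        return out


def build_graph(vertices: Sequence, edges: Iterable, parameters: Mapping | None = None,
                input_symbol: str | None = None, annotations: Mapping | None = None) -> LFGraph:
    """Validate and construct an :class:`LFGraph`.

    Parameters
    ----------
    vertices : sequence of identifiers (stringified)
    edges : iterable of (source, target, label) triples
    parameters : optional mapping of symbol name -> positive value
    input_symbol : optional name of the input concentration symbol

    Raises
    ------
    SelfLoop, DuplicateEdge, UnknownVertex, UnparseableLabel
    """
    vs = [_vname(v) for v in vertices]
    if len(set(vs)) != len(vs):
        raise GraphError("duplicate vertex identifiers")
    vset = set(vs)
    emap = {}
    for (s, t, lab) in edges:
        s, t = _vname(s), _vname(t)
        if s == t:
            raise SelfLoop(s)
        if s not in vset:
            raise UnknownVertex(s, edge=(s, t))
        if t not in vset:
            raise UnknownVertex(t, edge=(s, t))
        if (s, t) in emap:
            raise DuplicateEdge(s, t)
        emap[(s, t)] = parse_label(lab, edge=(s, t))
    ann = { _vname(k): v for k, v in (annotations or {}).items() }
    return LFGraph(vs, emap, dict(parameters or {}), input_symbol, ann)


def laplacian(g: LFGraph) -> sp.Matrix:
    """Symbolic column-sum-zero Laplacian; L[j, i] = label(i -> j)."""
    n = g.n
    L = sp.zeros(n, n)
    for (s, t), lab in g.edges.items():
        i, j = g.index(s), g.index(t)
        L[j, i] += lab
        L[i, i] -= lab
    return L


def numeric_laplacian(g: LFGraph, input_value=None) -> np.ndarray:
    """Numeric Laplacian with all parameters (and the input) bound.

    Raises :class:`UnboundParameter` if any symbol lacks a value.
    """
    missing = g.unbound_symbols(input_value)
    if missing:
        raise UnboundParameter(missing)
    subs = g.substitutions(input_value)
    n = g.n
    L = np.zeros((n, n))
    for (s, t), lab in g.edges.items():
        val = float(lab.xreplace(subs))
        i, j = g.index(s), g.index(t)
        L[j, i] += val
        L[i, i] -= val
    return L


def is_strongly_connected(g: LFGraph) -> bool:
    """True iff every ordered vertex pair is joined by a directed path."""
    if g.n <= 1:
        return True
    return nx.is_strongly_connected(g.to_networkx())


def is_reversible(g: LFGraph) -> bool:
    """True iff the edge set is closed under reversal."""
    return all((j, i) in g.edges for (i, j) in g.edges)


def propagate(g: LFGraph, u0, t_end: float, n_steps: int = 100,
              input_value=None, rtol: float = 1e-8, atol: float = 1e-10):
    """Integrate du/dt = L u from u0 on [0, t_end].

    Uses a stiff-capable implicit integrator (BDF) with the exact constant
    Jacobian L.  Returns ``(t, U)`` with ``U`` of shape (n_steps+1, N); each
    row sums to ``sum(u0)`` up to integration tolerance (conservation).
    """
    L = numeric_laplacian(g, input_value)
    u0 = np.asarray(u0, dtype=float)
    if u0.shape != (g.n,):
        raise ValueError(f"u0 must have shape ({g.n},)")
    if np.any(u0 < 0):
        raise ValueError("u0 must be non-negative")
    t_eval = np.linspace(0.0, t_end, n_steps + 1)
    sol = solve_ivp(lambda t, u: L @ u, (0.0, t_end), u0, method="BDF",
                    jac=lambda t, u: L, t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:  # pragma: no cover - defensive
        raise RuntimeError(f"integration failed: {sol.message}")
    return sol.t, sol.y.T
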