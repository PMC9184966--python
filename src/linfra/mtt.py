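"""Spanning-forest machinery and the Matrix-Tree prescription for steady states.

A spanning forest of G is a spanning subgraph that is acyclic when edge
directions are ignored and in which every vertex has at most one outgoing
edge; the vertices with no outgoing edge are its roots.  The Matrix-Tree
theorem expresses the canonical kernel element of the Laplacian as

    rho_i(G) = sum over spanning trees T rooted at i of prod of labels of T,

a sum of positive monomials.  For a strongly connected graph the kernel is
one-dimensional, so the steady state is rho up to normalisation:

    u_i* = rho_i / (rho_1 + ... + rho_N) * u_tot.

Enumeration here grows forests by assigning each non-root vertex one outgoing
edge and rejecting assignments that create cycles; each forest corresponds to
exactly one assignment, so the enumeration is duplicate-free by construction.
A brute-force all-edge-subset filter is kept as a small-instance oracle in
the test suite, not here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import sympy as sp

from .errors import (EmptyRootSet, NotSpanning, NotStronglyConnected,
                     UnboundParameter)
from .graph import LFGraph, is_strongly_connected, numeric_laplacian

__all__ = ["SpanningForest", "enumerate_spanning_forests", "count_rooted_trees",
           "rho", "rho_numeric", "steady_state", "steady_state_numeric"]


@dataclass(frozen=True)
class SpanningForest:
    """A spanning forest: frozen set of directed edges plus its root set."""
    edges: frozenset
    roots: frozenset

    def label_product(self, g: LFGraph) -> sp.Expr:
        out = sp.Integer(1)
        for e in self.edges:
            out *= g.edges[e]
        return out


def is_spanning_forest(g: LFGraph, edges, roots) -> bool:
    """Check the forest invariants directly (used as the testing oracle)."""
    edges = set(edges)
    roots = set(roots)
    out_deg = {v: 0 for v in g.vertices}
    for (s, t) in edges:
        if (s, t) not in g.edges:
            return False
        out_deg[s] += 1
    if any(d > 1 for d in out_deg.values()):
        return False
    if {v for v, d in out_deg.items() if d == 0} != roots:
        return False
    # acyclic ignoring direction <=> |E| = |V| - #components; with out-degree
    # <= 1 and roots as stated, it is enough that following out-edges from any
    # vertex terminates (no directed cycle) and that the undirected graph has
    # no cycle.  Union-find on the undirected support:
    parent = {v: v for v in g.vertices}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for (s, t) in edges:
        rs, rt = find(s), find(t)
        if rs == rt:
            return False
        parent[rs] = rt
    return True


def enumerate_spanning_forests(g: LFGraph, roots) -> list[SpanningForest]:
    """All spanning forests of ``g`` rooted at the vertex set ``roots``.

    Precondition: ``roots`` is a nonempty subset of the vertices.  For a
    strongly connected graph the result is nonempty.
    """
    roots = frozenset(str(r) for r in roots)
    if not roots:
        raise EmptyRootSet("root set must be nonempty")
    unknown = roots - set(g.vertices)
    if unknown:
        raise NotSpanning(f"roots not in graph: {sorted(unknown)}")
    non_roots = [v for v in g.vertices if v not in roots]
    out_edges = {v: [(v, t) for t in g.successors(v)] for v in non_roots}

    forests: list[SpanningForest] = []
    assignment: dict = {}

    def creates_cycle(v: str) -> bool:
        # follow assigned out-edges from v; a return to v is a cycle
        seen = {v}
        cur = assignment.get(v)
        while cur is not None:
            nxt = cur[1]
            if nxt in seen:
                return True
            seen.add(nxt)
            cur = assignment.get(nxt)
        return False

    def recurse(k: int):
        if k == len(non_roots):
            forests.append(SpanningForest(frozenset(assignment.values()), roots))
            return
        v = non_roots[k]
        for e in out_edges[v]:
            assignment[v] = e
            if not creates_cycle(v):
                recurse(k + 1)
            del assignment[v]

    recurse(0)
    return forests


def count_rooted_trees(g: LFGraph, root) -> int:
    """|Phi_{root}(g)| by the principal minor of the unit-label Laplacian.

    Exact integer arithmetic throughout (sympy integer determinant), so large
    hypercube counts are exact.
    """
    root = str(root)
    if not is_strongly_connected(g):
        raise NotStronglyConnected("tree counts need a strongly connected graph")
    n = g.n
    L = sp.zeros(n, n)
    for (s, t) in g.edges:
        i, j = g.index(s), g.index(t)
        L[j, i] += 1
        L[i, i] -= 1
    r = g.index(root)
    keep = [i for i in range(n) if i != r]
    minor = L[keep, keep]
    det = minor.det(method="berkowitz")
    return int(abs(det))


def rho(g: LFGraph, expand: bool = True) -> list[sp.Expr]:
    """Canonical Laplacian-kernel vector by spanning-tree enumeration.

    Entry i is the sum over spanning trees rooted at vertex i of the product
    of edge labels — a polynomial with positive coefficients in the graph's
    symbols.  Symbolic and exact; meant for small graphs (the numeric fast
    path is :func:`rho_numeric`).
    """
    if not is_strongly_connected(g):
        raise NotStronglyConnected("rho requires a strongly connected graph")
    out = []
    for v in g.vertices:
        trees = enumerate_spanning_forests(g, {v})
        total = sp.Add(*[t.label_product(g) for t in trees])
        out.append(sp.expand(total) if expand else total)
    return out


def rho_numeric(g: LFGraph, input_value=None, reference=None) -> np.ndarray:
    """Numeric kernel vector, scaled so the reference vertex entry is 1.

    Deletes the reference vertex's row and column of L and solves the
    resulting nonsingular system (the adjugate-column trick); falls back to
    an SVD nullspace when conditioning exceeds 1e12.
    """
    L = numeric_laplacian(g, input_value)
    n = g.n
    r = g.index(reference) if reference is not None else 0
    keep = [i for i in range(n) if i != r]
    A = L[np.ix_(keep, keep)]
    b = -L[np.ix_(keep, [r])].ravel()
    use_svd = False
    if n > 1:
        try:
            cond = np.linalg.cond(A)
            if not np.isfinite(cond) or cond > 1e12:
                use_svd = True
        except np.linalg.LinAlgError:  # pragma: no cover
            use_svd = True
    v = np.zeros(n)
    if n == 1:
        v[0] = 1.0
    elif not use_svd:
        x = np.linalg.solve(A, b)
        v[r] = 1.0
        v[keep] = x
    else:
        _, _, vt = np.linalg.svd(L)
        null = vt[-1]
        null = null / null[np.argmax(np.abs(null))]
        if null[r] == 0:  # pragma: no cover - strongly connected => positive
            raise NotStronglyConnected("kernel vector vanishes at reference")
        v = null / null[r]
    if np.any(v <= 0):
        # tiny negative round-off is conceivable near singularity
        if np.any(v < -1e-9 * np.max(np.abs(v))):
            raise NotStronglyConnected("kernel vector not positive; graph "
                                       "likely not strongly connected")
        v = np.clip(v, 0.0, None)
    return v


def steady_state(g: LFGraph, u_tot=1, mode: str = "symbolic",
                 input_value=None):
    """Normalised steady state of the Laplacian dynamics.

    mode='symbolic' returns a list of sympy expressions summing to u_tot
    (exact Matrix-Tree ratios); mode='numeric' uses the linear-algebra fast
    path and returns an ndarray.
    """
    if mode == "numeric":
        return steady_state_numeric(g, u_tot=u_tot, input_value=input_value)
    if mode != "symbolic":
        raise ValueError("mode must be 'symbolic' or 'numeric'")
    rs = rho(g)
    denom = sp.Add(*rs)
    return [sp.cancel(r / denom * u_tot) for r in rs]


def steady_state_numeric(g: LFGraph, u_tot: float = 1.0, input_value=None) -> np.ndarray:
    if not is_strongly_connected(g):
        raise NotStronglyConnected("steady state requires strong connectivity")
    v = rho_numeric(g, input_value)
    return v / v.sum() * u_tot
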