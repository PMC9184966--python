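"""Seeded fixture generators: every structure the package analyses can be
built here without external data.

Provides hypercube binding graphs (C_n and the regulated-recruitment
C_{m+1}), detailed-balanced (equilibrium) parametrizations, random strongly
connected and reversible graphs, the four-vertex conformation/binding square
used as the worked non-equilibrium example, and random enzyme mechanisms for
the modification-cycle machinery.

All randomness flows through a single ``numpy.random.default_rng(seed)``;
identical arguments give identical fixtures.
"""

from __future__ import annotations

import itertools

import numpy as np
import sympy as sp

from .graph import LFGraph, build_graph

__all__ = ["make_hypercube", "make_detailed_balanced", "make_allosteric_square",
           "make_random_strong", "make_random_reversible", "allosteric_square_edges"]


def _pattern_name(bits) -> str:
    return "".join(str(b) for b in bits)


def make_hypercube(n_sites: int, input_sites=(), per_site_labels: dict | None = None,
                   input_symbol: str = "x") -> LFGraph:
    """Hypercube binding graph C_n: 2^n vertices (binding patterns as
    bit-strings, site 0 is the least significant position), reversible edges
    flipping one site.

    Binding edges (0 -> 1 at a site in ``input_sites``) carry the input
    symbol as a factor.  Labels default to one symbolic parameter per
    directed edge (``kon_<site>_<pattern>`` / ``koff_<site>_<pattern>``);
    ``per_site_labels`` can map ``(site, "on"|"off")`` to a shared symbol
    name instead.  Vertex annotations hold the binding bit-vectors consumed
    by the coarse-graining machinery.
    """
    input_sites = set(input_sites)
    pats = [tuple((v >> k) & 1 for k in range(n_sites)) for v in range(2 ** n_sites)]
    names = [_pattern_name(p) for p in pats]
    edges = []
    for p in pats:
        v = _pattern_name(p)
        for site in range(n_sites):
            if p[site] == 0:
                q = list(p)
                q[site] = 1
                w = _pattern_name(q)
                if per_site_labels and (site, "on") in per_site_labels:
                    on = per_site_labels[(site, "on")]
                    off = per_site_labels[(site, "off")]
                else:
                    on = f"kon_{site}_{v}"
                    off = f"koff_{site}_{v}"
                on_label = f"{on}*{input_symbol}" if site in input_sites else on
                edges.append((v, w, on_label))
                edges.append((w, v, off))
    ann = dict(zip(names, pats))
    return build_graph(names, edges, input_symbol=input_symbol if input_sites else None,
                       annotations=ann)


def make_detailed_balanced(structure, seed: int = 0, r: float = 3.0) -> LFGraph:
    """Equilibrium (detailed-balanced) parametrization of a reversible
    structure.

    ``structure`` is an LFGraph whose edge set is used (labels ignored,
    except that a factor of the input symbol on a binding edge is kept).
    Draws vertex potentials phi_i and symmetric edge scales s_ij log-uniform
    in [10^-r, 10^r] and sets l(i -> j) = s_ij * exp((phi_i - phi_j)/2), so
    every cycle's label-ratio product is exactly one up to float rounding
    and mu_i = exp(phi_1 - phi_i).
    """
    rng = np.random.default_rng(seed)
    g = structure
    ln10 = np.log(10.0)
    phi = {v: rng.uniform(-r, r) * ln10 for v in g.vertices}
    x = sp.Symbol(g.input_symbol) if g.input_symbol else None
    scale = {}
    edges = []
    for (i, j), lab in g.edges.items():
        key = (i, j) if i < j else (j, i)
        if key not in scale:
            scale[key] = 10.0 ** rng.uniform(-r, r)
        val = scale[key] * np.exp((phi[i] - phi[j]) / 2.0)
        expr = sp.Float(val)
        if x is not None and x in lab.free_symbols:
            expr = expr * x
        edges.append((i, j, expr))
    return build_graph(g.vertices, edges, input_symbol=g.input_symbol,
                       annotations=g.annotations)


def allosteric_square_edges():
    """Edge list of the two-conformation, one-binding-site square.

    Vertices 1, 2 are the unbound conformations and 3, 4 the bound ones;
    1<->3 and 2<->4 are the binding transitions carrying the input x.  The
    parameter placement is the unique one (up to the square's symmetry) for
    which the single cycle's condition reads k1*k2*k3*k4 = k5*k6*k7*k8 and
    the equilibrium response is (k2/k8)(1 + k3/k7)x over
    (1 + k5/k1) + (k2/k8)(1 + k3/k7)x.
    """
    return [("1", "2", "k5"), ("2", "1", "k1"),
            ("1", "3", "k2*x"), ("3", "1", "k8"),
            ("2", "4", "k6*x"), ("4", "2", "k4"),
            ("3", "4", "k3"), ("4", "3", "k7")]


def make_allosteric_square(params: dict | None = None, equilibrium: bool = False) -> LFGraph:
    """The worked-example square: allosteric biomolecule with two
    conformations and one ligand site.

    With ``equilibrium=True``, k8 is overwritten to k1*k2*k3*k4/(k5*k6*k7)
    so the cycle condition holds exactly.  Annotations mark the bound
    vertices (site 0 of a one-site pattern).
    """
    params = dict(params or {})
    if equilibrium and params:
        needed = ["k1", "k2", "k3", "k4", "k5", "k6", "k7"]
        if all(k in params for k in needed):
            # exact rational ratio so the cycle identity holds exactly and
            # the equilibrium response cancels to degree 1 symbolically
            r = {k: sp.Rational(params[k]) for k in needed}
            params["k8"] = (r["k1"] * r["k2"] * r["k3"] * r["k4"]
                            / (r["k5"] * r["k6"] * r["k7"]))
    ann = {"1": (0,), "2": (0,), "3": (1,), "4": (1,)}
    return build_graph(["1", "2", "3", "4"], allosteric_square_edges(), parameters=params,
                       input_symbol="x", annotations=ann)


def make_random_strong(n: int, seed: int = 0, extra_edges: int = 0,
                       r: float = 1.0) -> LFGraph:
    """Random strongly connected graph with numeric labels.

    Starts from a random Hamiltonian cycle (guaranteeing strong
    connectivity) and adds ``extra_edges`` distinct random edges.  Labels
    log-uniform in [10^-r, 10^r].
    """
    rng = np.random.default_rng(seed)
    verts = [str(i + 1) for i in range(n)]
    order = list(rng.permutation(n))
    pairs = {(verts[order[i]], verts[order[(i + 1) % n]]) for i in range(n)}
    candidates = [(a, b) for a in verts for b in verts if a != b and (a, b) not in pairs]
    rng.shuffle(candidates)
    pairs |= set(candidates[:extra_edges])
    edges = [(a, b, float(10.0 ** rng.uniform(-r, r))) for (a, b) in sorted(pairs)]
    return build_graph(verts, edges)


def make_random_reversible(n: int, seed: int = 0, extra_pairs: int = 0,
                           r: float = 1.0) -> LFGraph:
    """Random reversible strongly connected graph (generic labels, so it is
    non-equilibrium with probability one once it contains a cycle)."""
    rng = np.random.default_rng(seed)
    verts = [str(i + 1) for i in range(n)]
    # random spanning tree, then extra reversible pairs
    pairs = set()
    attached = [verts[0]]
    for v in verts[1:]:
        u = attached[rng.integers(len(attached))]
        pairs.add((u, v))
        attached.append(v)
    candidates = [(a, b) for i, a in enumerate(verts) for b in verts[i + 1:]
                  if a != b and (a, b) not in pairs]
    rng.shuffle(candidates)
    pairs |= set(candidates[:extra_pairs])
    edges = []
    for (a, b) in sorted(pairs):
        edges.append((a, b, float(10.0 ** rng.uniform(-r, r))))
        edges.append((b, a, float(10.0 ** rng.uniform(-r, r))))
    return build_graph(verts, edges)
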