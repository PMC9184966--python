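"""Partition-based coarse graining of reversible graphs.

Given a partition of the vertices of a strongly connected reversible graph G
into blocks G_1, ..., G_s, the coarse-grained graph C(G) has one vertex per
block, an edge w -> z whenever some member edge crosses from G_w to G_z, and
labels

    l(w -> z) = Q * sum over j in G_z of rho_j(G),

with Q an arbitrary dimension-fixing constant that cancels at steady state.
With this labelling C(G) always satisfies the cycle condition — even when G
does not — and its steady state aggregates exactly:

    u_w*(C(G)) = sum over i in G_w of u_i*(G).

This is a steady-state construction only; C(G) is not expected to
approximate the dynamics of G at finite time.

For a graph at equilibrium, any output function on G pushes forward to a
non-negative, input-independent linear combination of coarse steady-state
probabilities; the constructive coefficients used here are the
mu-weighted block averages of the fine coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (InvalidPartition, MissingAnnotation, NotAtEquilibrium,
                     NotReversible, NotStronglyConnected)
from .graph import LFGraph, build_graph, is_reversible, is_strongly_connected
from .mtt import rho_numeric, steady_state_numeric
from .thermo import equilibrium_basis, satisfies_cycle_condition

__all__ = ["Partition", "CoarseGraph", "coarse_grain",
           "binding_pattern_partition", "pushforward_output",
           "coarse_steady_state"]


@dataclass
class Partition:
    """Disjoint nonempty vertex blocks covering the whole vertex set."""
    blocks: list

    def __post_init__(self):
        self.blocks = [[str(v) for v in b] for b in self.blocks]

    def validate(self, g: LFGraph) -> None:
        seen = set()
        for b in self.blocks:
            if not b:
                raise InvalidPartition("empty block")
            for v in b:
                if v in seen:
                    raise InvalidPartition(f"vertex {v!r} in more than one block")
                if v not in g._index:
                    raise InvalidPartition(f"unknown vertex {v!r}")
                seen.add(v)
        if seen != set(g.vertices):
            missing = set(g.vertices) - seen
            raise InvalidPartition(f"vertices not covered: {sorted(missing)}")

    def block_of(self) -> dict:
        return {v: w for w, b in enumerate(self.blocks) for v in b}


@dataclass
class CoarseGraph:
    """Coarse-grained graph plus provenance back to the fine graph."""
    graph: LFGraph
    partition: Partition
    Q: float = 1.0
    missing_hypercube_edges: list = field(default_factory=list)


def coarse_grain(g: LFGraph, p: Partition, Q: float = 1.0,
                 input_value=None) -> CoarseGraph:
    """Coarse-grain ``g`` by the partition ``p`` with the rho labelling.

    Labels are evaluated numerically (parameters must be bound; the input
    symbol, if any, is bound at ``input_value``).  Block w is named
    ``"B<w>"`` in the coarse graph, in partition order.
    """
    if not is_strongly_connected(g):
        raise NotStronglyConnected("coarse graining requires strong connectivity")
    if not is_reversible(g):
        raise NotReversible("coarse graining requires a reversible graph")
    p.validate(g)
    block_of = p.block_of()
    r = rho_numeric(g, input_value=input_value)
    block_rho = np.zeros(len(p.blocks))
    for v, w in block_of.items():
        block_rho[w] += r[g.index(v)]
    crossing = set()
    for (i, j) in g.edges:
        w, z = block_of[i], block_of[j]
        if w != z:
            crossing.add((w, z))
    names = [f"B{w}" for w in range(len(p.blocks))]
    edges = [(names[w], names[z], Q * block_rho[z]) for (w, z) in sorted(crossing)]
    cg = build_graph(names, edges)
    return CoarseGraph(cg, p, Q)


def binding_pattern_partition(g: LFGraph, site_subset) -> Partition:
    """Partition a hypercube-structured graph by its binding pattern on a
    subset of sites.

    Vertex annotations must carry a bit-vector (tuple/list of 0/1) per
    vertex, as produced by the hypercube fixtures.  Blocks are the
    equivalence classes of the pattern restricted to ``site_subset``, in
    lexicographic pattern order.
    """
    site_subset = sorted(site_subset)
    patterns: dict = {}
    for v in g.vertices:
        if v not in g.annotations:
            raise MissingAnnotation(f"vertex {v!r} lacks a binding annotation")
        bits = tuple(g.annotations[v])
        key = tuple(bits[s] for s in site_subset)
        patterns.setdefault(key, []).append(v)
    return Partition([patterns[k] for k in sorted(patterns)])


def pushforward_output(g: LFGraph, output_coeffs, p: Partition,
                       reference_input: float = 1.0, tol: float = 1e-9):
    """Push an output function through a coarse graining at equilibrium.

    Returns coarse coefficients lambda_w >= 0 such that
    sum_w lambda_w u_w*(C(G)) equals sum_i lambda_i u_i*(G) for every input
    value, provided G satisfies the cycle condition.  The constructive
    choice is the mu-weighted average of the fine coefficients over each
    block, evaluated at ``reference_input`` (input independence is a
    consequence of equilibrium, verified in tests, not assumed here).
    """
    ok, cyc = satisfies_cycle_condition(g, tol=tol, input_value=reference_input)
    if not ok:
        raise NotAtEquilibrium(cycle=cyc)
    lam = np.asarray(output_coeffs, dtype=float)
    if lam.shape != (g.n,) or np.any(lam < 0):
        raise ValueError("output_coeffs must be non-negative, one per vertex")
    p.validate(g)
    mu = equilibrium_basis(g, input_value=reference_input)
    out = np.zeros(len(p.blocks))
    for w, block in enumerate(p.blocks):
        idx = [g.index(v) for v in block]
        out[w] = float(np.dot(lam[idx], mu[idx]) / np.sum(mu[idx]))
    return out


def coarse_steady_state(g: LFGraph, p: Partition, Q: float = 1.0,
                        u_tot: float = 1.0, input_value=None) -> np.ndarray:
    """Steady state of C(G), in partition block order."""
    cg = coarse_grain(g, p, Q=Q, input_value=input_value)
    return steady_state_numeric(cg.graph, u_tot=u_tot)
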