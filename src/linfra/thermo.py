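"""Thermodynamic layer: cycle condition, detailed balance, equilibrium states.

A reversible graph can reach thermodynamic equilibrium iff the product of
label ratios around every cycle of reversible edges equals one (the
cycle / Wegscheider condition).  When it holds, the equilibrium steady state
follows from path products alone: mu_i is the product of forward/backward
label ratios along any reversible path from the reference vertex (vertex 1
by convention, mu_1 = 1), and

    u_i* = mu_i / (mu_1 + ... + mu_N) * u_tot,

the Boltzmann prescription with the denominator as partition function.  Away
from equilibrium the full Matrix-Tree sum (mtt.rho) is required instead.

The log label ratio of a reversible edge pair is the total entropy change of
that transition in units of k_B (local detailed balance); only the total is
computed here, not its environment/internal decomposition.
"""

from __future__ import annotations

import math
import warnings

import networkx as nx
import numpy as np
import sympy as sp

from .errors import (IrreversibleStep, NoRoot, NotAtEquilibrium,
                     NotReversible, NotStronglyConnected)
from .graph import LFGraph, is_reversible, is_strongly_connected
from .mtt import steady_state_numeric

__all__ = ["path_product", "satisfies_cycle_condition", "equilibrium_basis",
           "equilibrium_steady_state", "detailed_balance_residuals",
           "edge_entropy", "solve_ligand_conservation"]


def _num_label(g: LFGraph, i, j, input_value=None) -> float:
    val = g.edges[(i, j)].xreplace(g.substitutions(input_value))
    return float(val)


def path_product(g: LFGraph, path, numeric: bool = True, input_value=None):
    """mu(P): product of forward/backward label ratios along a reversible path.

    ``path`` is a vertex sequence i1, ..., ik with both directions of every
    consecutive pair present in the graph.  Multiplicative under
    concatenation; the reversed path gives the reciprocal.
    """
    path = [str(v) for v in path]
    out = 1.0 if numeric else sp.Integer(1)
    for a, b in zip(path[:-1], path[1:]):
        if (a, b) not in g.edges or (b, a) not in g.edges:
            raise IrreversibleStep(a, b)
        if numeric:
            out *= _num_label(g, a, b, input_value) / _num_label(g, b, a, input_value)
        else:
            out *= g.edges[(a, b)] / g.edges[(b, a)]
    return out


def _cycle_basis(g: LFGraph) -> list[list]:
    """Fundamental cycles of the undirected support, as closed vertex lists."""
    und = nx.Graph()
    und.add_nodes_from(g.vertices)
    und.add_edges_from(g.edges)
    cycles = nx.cycle_basis(und)
    return [c + [c[0]] for c in cycles]


def satisfies_cycle_condition(g: LFGraph, tol: float = 1e-9,
                              input_value=None):
    """Check |ln mu(C)| < tol on a fundamental cycle basis.

    Returns ``(ok, violating_cycle)`` where the cycle is the first basis
    cycle breaking the condition (closed vertex list), or None.  The
    tolerance is on the log product, making the check direction-symmetric.
    """
    if not is_reversible(g):
        raise NotReversible("cycle condition is defined for reversible graphs")
    if input_value is None and g.input_symbol is not None:
        input_value = 1.0  # mu is evaluated at a reference input; x cancels
        # in cycles only if binding/unbinding is matched, which the condition
        # itself is checking — any positive reference works.
    worst = 0.0
    for cyc in _cycle_basis(g):
        mu = path_product(g, cyc, numeric=True, input_value=input_value)
        log_mu = abs(math.log(mu))
        worst = max(worst, log_mu)
        if log_mu >= tol:
            return False, cyc
    return True, None


def equilibrium_basis(g: LFGraph, input_value=None, reference=None) -> np.ndarray:
    """mu_i relative to the reference vertex, along a spanning tree of the
    reversible support.  Well defined only under the cycle condition."""
    und = nx.Graph()
    und.add_nodes_from(g.vertices)
    und.add_edges_from((i, j) for (i, j) in g.edges if (j, i) in g.edges)
    ref = str(reference) if reference is not None else g.vertices[0]
    if not nx.is_connected(und):
        raise NotStronglyConnected("reversible support is not connected")
    mu = np.empty(g.n)
    mu[g.index(ref)] = 1.0
    # BFS from the reference, accumulating log ratios for stability
    log_mu = {ref: 0.0}
    for parent, child in nx.bfs_edges(und, ref):
        step = math.log(_num_label(g, parent, child, input_value)) \
             - math.log(_num_label(g, child, parent, input_value))
        log_mu[child] = log_mu[parent] + step
    logs = np.array([log_mu[v] for v in g.vertices])
    if logs.max() - logs.min() > math.log(1e12):
        warnings.warn("mu ratios span more than 1e12; equilibrium state may "
                      "be ill-conditioned", RuntimeWarning)
    return np.exp(logs)


def equilibrium_steady_state(g: LFGraph, u_tot: float = 1.0,
                             input_value=None, tol: float = 1e-9) -> np.ndarray:
    """Equilibrium steady state from path products (Boltzmann prescription).

    Raises :class:`NotAtEquilibrium` if the cycle condition fails at ``tol``.
    """
    ok, cyc = satisfies_cycle_condition(g, tol=tol, input_value=input_value)
    if not ok:
        mu = path_product(g, cyc, numeric=True, input_value=input_value)
        raise NotAtEquilibrium(cycle=cyc, log_mu=abs(math.log(mu)))
    mu = equilibrium_basis(g, input_value)
    return mu / mu.sum() * u_tot


def detailed_balance_residuals(g: LFGraph, u, input_value=None) -> dict:
    """Flux residuals r_ij = u_i l(i->j) - u_j l(j->i) per reversible pair.

    All residuals vanish iff the state is an equilibrium steady state.
    Antisymmetric: the (j, i) residual is the negative of (i, j).
    """
    if not is_reversible(g):
        raise NotReversible("detailed balance is defined for reversible graphs")
    u = np.asarray(u, dtype=float)
    out = {}
    for (i, j) in g.reversed_pairs():
        r = (u[g.index(i)] * _num_label(g, i, j, input_value)
             - u[g.index(j)] * _num_label(g, j, i, input_value))
        out[(i, j)] = r
    return out


def edge_entropy(g: LFGraph, i, j, input_value=None) -> float:
    """Total entropy change of transition i -> j, in units of k_B.

    ln of the label ratio l(i->j)/l(j->i); antisymmetric in (i, j).
    """
    i, j = str(i), str(j)
    if (i, j) not in g.edges or (j, i) not in g.edges:
        raise IrreversibleStep(i, j)
    return math.log(_num_label(g, i, j, input_value)) \
         - math.log(_num_label(g, j, i, input_value))


def solve_ligand_conservation(g: LFGraph, ligand_vertices, L_tot: float,
                              u_tot: float = 1.0, xtol: float = 1e-12):
    """Close the ligand conservation law at steady state.

    With the input symbol interpreted as free-ligand concentration [L] and
    ``ligand_vertices`` the vertices where L is bound, solves

        L_tot = [L] + sum over ligand vertices of u_i*([L])

    for the unique root in (0, L_tot].  [L] + bound([L]) - L_tot is monotone
    increasing in [L], so Brent bracketing on (0, L_tot] is safe.  Returns
    ``([L]*, steady_state_vector)``.
    """
    from scipy.optimize import brentq

    if g.input_symbol is None:
        raise NoRoot("graph has no input symbol to interpret as [L]")
    lig_idx = [g.index(v) for v in ligand_vertices]

    def bound(x):
        u = steady_state_numeric(g, u_tot=u_tot, input_value=x)
        return float(np.sum(u[lig_idx]))

    if u_tot == 0 or not lig_idx:
        u = (steady_state_numeric(g, u_tot=u_tot, input_value=L_tot)
             if u_tot else np.zeros(g.n))
        return L_tot, u

    def h(x):
        return x + bound(x) - L_tot

    lo = L_tot * 1e-16
    if h(lo) > 0:
        # essentially all ligand is bound even at vanishing free ligand
        lo = L_tot * 1e-30
        if h(lo) > 0:
            raise NoRoot("no free-ligand root found in (0, L_tot]")
    x_star = brentq(h, lo, L_tot, xtol=xtol * max(L_tot, 1.0))
    return x_star, steady_state_numeric(g, u_tot=u_tot, input_value=x_star)
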