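"""Enzyme mechanisms, aggregated parameters and the reduction of a
modification-demodification cycle to enzyme conservation equations.

An enzyme mechanism is any reaction network over a free enzyme X and
intermediate complexes Y_i built from the grammar

    binding:     X + S* -> Y_i        (rate * [S*] on the edge label)
    conversion:  Y_i -> Y_j
    release:     Y_k -> X + S*

with S* one of the substrate forms S0 (unmodified) or S1 (modified).  The
induced labelled graph (vertices X and the Y_i) must be strongly connected.
Because substrate symbols appear only on edges leaving X, the Matrix-Tree
vector of the enzyme graph is linear in [S0], [S1] at the intermediates and
constant at X.  Dividing by the constant gives the aggregated parameters:

    [Y_i]* = (kappa0_Yi [S0]* + kappa1_Yi [S1]*) [X]*      (rgMMCs)
    c01 = sum over S1-release edges of rate * kappa0_source (tgCE, forward)
    c10 = sum over S0-release edges of rate * kappa1_source (tgCE, reverse)
    kappa0 = sum_i kappa0_Yi,  kappa1 = sum_i kappa1_Yi     (trgMMCs)

A mechanism is strongly irreversible iff kappa1 = 0 (product cannot rebind)
and weakly irreversible iff kappa1 > 0 and c10 = 0 (product rebinds but is
never converted back).

For the two-enzyme cycle (forward enzyme E, reverse enzyme F) the
steady-state substrate ratio is

    [S1]*/[S0]* = (c01E [E]* + c01F [F]*) / (c10E [E]* + c10F [F]*),

and substituting the substrate conservation law reduces the whole network
to two simultaneous equations E_tot = R_E([E]*, [F]*), F_tot = R_F([E]*,
[F]*) — every other steady-state variable is a rational function of the
free enzyme concentrations.  ``solve_cycle`` finds all positive roots;
``ode_oracle`` integrates the full mass-action network as an independent
check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import sympy as sp
from scipy.integrate import solve_ivp
from scipy.optimize import root as _scipy_root

from .errors import (GrammarViolation, LinearityViolation, NoRootFound,
                     NotConverged, NotStronglyConnected, ZeroActivity)
from .graph import LFGraph, build_graph, is_strongly_connected
from .mtt import rho

__all__ = ["Reaction", "EnzymeMechanism", "AggregatedParams",
           "ModificationCycle", "mechanism_graph", "aggregated_params",
           "substrate_graph", "reduced_system", "solve_cycle", "ode_oracle",
           "CycleState", "mm_mechanism", "reversible_mm_mechanism",
           "random_order_bibi_mechanism", "deadend_phosphatase_mechanism",
           "random_cycle"]

_SUBSTRATES = ("S0", "S1")


@dataclass(frozen=True)
class Reaction:
    """One grammar reaction.  kind in {'binding', 'conversion', 'release'}.

    binding:    source = enzyme, target = intermediate, substrate set
    conversion: source, target = intermediates
    release:    source = intermediate, target = enzyme, substrate set
    """
    kind: str
    source: str
    target: str
    rate: str
    substrate: str | None = None


@dataclass
class EnzymeMechanism:
    enzyme: str
    intermediates: list
    reactions: list
    parameters: dict = field(default_factory=dict)

    def __post_init__(self):
        self._validate()

    def _validate(self):
        inter = set(self.intermediates)
        if self.enzyme in inter:
            raise GrammarViolation(self.enzyme, "enzyme symbol reused as intermediate")
        for rx in self.reactions:
            if rx.kind == "binding":
                if rx.source != self.enzyme or rx.target not in inter:
                    raise GrammarViolation(rx, "binding must be enzyme + S* -> intermediate")
                if rx.substrate not in _SUBSTRATES:
                    raise GrammarViolation(rx, f"substrate must be one of {_SUBSTRATES}")
            elif rx.kind == "conversion":
                if rx.source not in inter or rx.target not in inter:
                    raise GrammarViolation(rx, "conversion must join two intermediates")
                if rx.substrate is not None:
                    raise GrammarViolation(rx, "substrate cannot appear on a "
                                               "conversion (uncoupling condition)")
            elif rx.kind == "release":
                if rx.source not in inter or rx.target != self.enzyme:
                    raise GrammarViolation(rx, "release must be intermediate -> enzyme + S*")
                if rx.substrate not in _SUBSTRATES:
                    raise GrammarViolation(rx, f"substrate must be one of {_SUBSTRATES}")
            else:
                raise GrammarViolation(rx, f"unknown reaction kind {rx.kind!r}")
            if rx.source == rx.target:
                raise GrammarViolation(rx, "self loop")


def mechanism_graph(m: EnzymeMechanism) -> LFGraph:
    """Labelled graph of an enzyme mechanism.

    Vertices are the enzyme states (free enzyme + intermediates); binding
    edges carry rate * substrate-concentration symbol.  Parallel reactions
    between the same ordered state pair are merged by summing labels (the
    graph is simple).  Raises :class:`NotStronglyConnected` if the mechanism
    cannot cycle through all its states.
    """
    verts = [m.enzyme] + list(m.intermediates)
    lab: dict = {}
    for rx in m.reactions:
        if rx.kind == "binding":
            expr = sp.Symbol(rx.rate) * sp.Symbol(rx.substrate)
        else:
            expr = sp.Symbol(rx.rate)
        key = (rx.source, rx.target)
        lab[key] = lab.get(key, sp.Integer(0)) + expr
    g = build_graph(verts, [(s, t, e) for (s, t), e in lab.items()],
                    parameters=m.parameters)
    if not is_strongly_connected(g):
        raise NotStronglyConnected(
            f"mechanism graph of {m.enzyme} is not strongly connected")
    return g


@dataclass
class AggregatedParams:
    """Symbolic aggregated parameters of one mechanism.

    kappa0/kappa1 map intermediate -> rgMMC (concentration^-1 scale);
    c01/c10 are the tgCEs; kappa0_tot/kappa1_tot the trgMMCs.
    """
    enzyme: str
    kappa0: dict
    kappa1: dict
    c01: sp.Expr
    c10: sp.Expr

    @property
    def kappa0_tot(self) -> sp.Expr:
        return sp.Add(*self.kappa0.values()) if self.kappa0 else sp.Integer(0)

    @property
    def kappa1_tot(self) -> sp.Expr:
        return sp.Add(*self.kappa1.values()) if self.kappa1 else sp.Integer(0)

    def numeric(self, parameters: dict) -> "NumericAggregated":
        subs = {sp.Symbol(k): v for k, v in parameters.items()}

        def ev(e):
            return float(sp.simplify(e).xreplace(subs))

        return NumericAggregated(
            enzyme=self.enzyme,
            kappa0={y: ev(e) for y, e in self.kappa0.items()},
            kappa1={y: ev(e) for y, e in self.kappa1.items()},
            c01=ev(self.c01), c10=ev(self.c10))

    def is_strongly_irreversible(self, product: str = "S1") -> bool:
        """Product cannot rebind: the product-direction trgMMC vanishes.
        ``product`` names the mechanism's net product (S1 for the forward
        leg of a cycle, S0 for the reverse leg)."""
        kp = self.kappa1_tot if product == "S1" else self.kappa0_tot
        return sp.simplify(kp) == 0

    def is_weakly_irreversible(self, product: str = "S1") -> bool:
        """Product rebinds but is never converted back to substrate."""
        back = self.c10 if product == "S1" else self.c01
        return (not self.is_strongly_irreversible(product)
                and sp.simplify(back) == 0)


@dataclass
class NumericAggregated:
    enzyme: str
    kappa0: dict
    kappa1: dict
    c01: float
    c10: float

    @property
    def kappa0_tot(self) -> float:
        return sum(self.kappa0.values())

    @property
    def kappa1_tot(self) -> float:
        return sum(self.kappa1.values())


def aggregated_params(m: EnzymeMechanism) -> AggregatedParams:
    """Extract rgMMCs, tgCEs and trgMMCs from the mechanism graph.

    Computes the Matrix-Tree vector of the enzyme graph symbolically,
    asserts that the free-enzyme entry is independent of [S0], [S1] and that
    every intermediate entry is homogeneous linear in them (guaranteed by
    the grammar; violation signals a bug), and reads the aggregated
    parameters off the coefficients.
    """
    g = mechanism_graph(m)
    s0, s1 = sp.Symbol("S0"), sp.Symbol("S1")
    rs = rho(g)
    rho_x = rs[g.index(m.enzyme)]
    if rho_x.has(s0) or rho_x.has(s1):
        raise LinearityViolation("rho at the free enzyme involves substrate "
                                 "concentrations")
    kappa0, kappa1 = {}, {}
    for y in m.intermediates:
        ry = sp.expand(rs[g.index(y)])
        poly = sp.Poly(ry, s0, s1)
        for monom, coeff in poly.terms():
            if sum(monom) != 1:
                raise LinearityViolation(
                    f"rho at {y} is not homogeneous linear in [S0], [S1]")
        k0 = sp.cancel(poly.coeff_monomial(s0) / rho_x)
        k1 = sp.cancel(poly.coeff_monomial(s1) / rho_x)
        kappa0[y] = k0
        kappa1[y] = k1
    c01 = sp.Integer(0)
    c10 = sp.Integer(0)
    for rx in m.reactions:
        if rx.kind != "release":
            continue
        if rx.substrate == "S1":
            c01 += sp.Symbol(rx.rate) * kappa0[rx.source]
        else:
            c10 += sp.Symbol(rx.rate) * kappa1[rx.source]
    return AggregatedParams(enzyme=m.enzyme, kappa0=kappa0, kappa1=kappa1,
                            c01=sp.cancel(c01), c10=sp.cancel(c10))


# ---------------------------------------------------------------------------
# the two-enzyme modification cycle
# ---------------------------------------------------------------------------

@dataclass
class ModificationCycle:
    forward: EnzymeMechanism           # converts S0 -> S1 (net)
    reverse: EnzymeMechanism           # converts S1 -> S0 (net)
    E_tot: float
    F_tot: float
    S_tot: float

    def __post_init__(self):
        if self.forward.enzyme == self.reverse.enzyme:
            raise GrammarViolation(self.forward.enzyme,
                                   "forward and reverse enzymes must differ")
        common = set(self.forward.intermediates) & set(self.reverse.intermediates)
        if common:
            raise GrammarViolation(sorted(common),
                                   "mechanisms share intermediate names")

    def aggregated(self):
        return aggregated_params(self.forward), aggregated_params(self.reverse)

    def numeric_aggregated(self):
        ae, af = self.aggregated()
        return (ae.numeric(self.forward.parameters),
                af.numeric(self.reverse.parameters))


def substrate_graph(cycle: ModificationCycle, E_star: float, F_star: float) -> LFGraph:
    """Two-vertex substrate graph at given free-enzyme concentrations.

    Labels l(S0 -> S1) = c01E*E + c01F*F and l(S1 -> S0) = c10E*E + c10F*F;
    a direction with a zero label is omitted (absorbing).  Raises
    :class:`ZeroActivity` if both directions vanish.
    """
    ae, af = cycle.numeric_aggregated()
    fwd = ae.c01 * E_star + af.c01 * F_star
    bwd = ae.c10 * E_star + af.c10 * F_star
    if fwd == 0 and bwd == 0:
        raise ZeroActivity("no enzyme activity in either direction")
    edges = []
    if fwd > 0:
        edges.append(("S0", "S1", float(fwd)))
    if bwd > 0:
        edges.append(("S1", "S0", float(bwd)))
    return build_graph(["S0", "S1"], edges)


def _closure(ae: NumericAggregated, af: NumericAggregated, S_tot: float):
    """Substrate concentrations as functions of free enzymes.

    Uses the homogeneous form S0 ~ D0, S1 ~ D1 with D1 = c01E*E + c01F*F
    and D0 = c10E*E + c10F*F, so fully irreversible limits (D0 = 0) need no
    special casing.
    """

    def substrate(E, F):
        D1 = ae.c01 * E + af.c01 * F
        D0 = ae.c10 * E + af.c10 * F
        if D0 == 0 and D1 == 0:
            raise ZeroActivity("no enzyme activity in either direction")
        denom = (D0 + D1
                 + (ae.kappa0_tot * D0 + ae.kappa1_tot * D1) * E
                 + (af.kappa0_tot * D0 + af.kappa1_tot * D1) * F)
        S0 = S_tot * D0 / denom
        S1 = S_tot * D1 / denom
        return S0, S1

    return substrate


def reduced_system(cycle: ModificationCycle):
    """Symbolic enzyme conservation functions (R_E, R_F, E, F).

    R_E(E, F) and R_F(E, F) are the totals implied by free enzyme
    concentrations E, F after eliminating the substrate and intermediate
    variables; the steady states are the solutions of R_E = E_tot,
    R_F = F_tot.  Returned as sympy rational expressions in the symbols E, F
    (cleared forms are used internally by :func:`solve_cycle`).
    """
    ae, af = cycle.numeric_aggregated()
    E, F = sp.symbols("E F", positive=True)
    D1 = ae.c01 * E + af.c01 * F
    D0 = ae.c10 * E + af.c10 * F
    denom = (D0 + D1
             + (ae.kappa0_tot * D0 + ae.kappa1_tot * D1) * E
             + (af.kappa0_tot * D0 + af.kappa1_tot * D1) * F)
    S0 = cycle.S_tot * D0 / denom
    S1 = cycle.S_tot * D1 / denom
    R_E = sp.cancel(E * (1 + ae.kappa0_tot * S0 + ae.kappa1_tot * S1))
    R_F = sp.cancel(F * (1 + af.kappa0_tot * S0 + af.kappa1_tot * S1))
    return R_E, R_F, E, F


@dataclass
class CycleState:
    """Complete steady state of a modification cycle."""
    E_free: float
    F_free: float
    S0: float
    S1: float
    intermediates: dict        # name -> concentration

    def as_dict(self) -> dict:
        out = {"E": self.E_free, "F": self.F_free, "S0": self.S0, "S1": self.S1}
        out.update(self.intermediates)
        return out


def _full_state(cycle: ModificationCycle, ae, af, E, F) -> CycleState:
    sub = _closure(ae, af, cycle.S_tot)
    S0, S1 = sub(E, F)
    inter = {}
    for y, k0 in ae.kappa0.items():
        inter[y] = (k0 * S0 + ae.kappa1[y] * S1) * E
    for y, k0 in af.kappa0.items():
        inter[y] = (k0 * S0 + af.kappa1[y] * S1) * F
    return CycleState(E_free=E, F_free=F, S0=S0, S1=S1, intermediates=inter)


def solve_cycle(cycle: ModificationCycle, grid: int = 200,
                residual_tol: float = 1e-9, dedup_tol: float = 1e-6) -> list[CycleState]:
    """All positive roots of the reduced system in (0, E_tot] x (0, F_tot].

    Dense log-grid scan of the residuals followed by Newton polishing in
    log coordinates (so iterates stay positive); roots deduplicated at
    ``dedup_tol`` relative.  Every returned state satisfies the three
    conservation laws by construction of the back-substitution.
    """
    ae, af = cycle.numeric_aggregated()
    sub = _closure(ae, af, cycle.S_tot)
    Etot, Ftot, Stot = cycle.E_tot, cycle.F_tot, cycle.S_tot
    scale = max(Etot, Ftot, 1e-30)

    def resid(E, F):
        S0, S1 = sub(E, F)
        g1 = E * (1 + ae.kappa0_tot * S0 + ae.kappa1_tot * S1) - Etot
        g2 = F * (1 + af.kappa0_tot * S0 + af.kappa1_tot * S1) - Ftot
        return g1, g2

    # vectorised residual norm on a log grid
    le = np.log10(Etot)
    lf = np.log10(Ftot)
    Eg = np.logspace(le - 8, le, grid)
    Fg = np.logspace(lf - 8, lf, grid)
    EE, FF = np.meshgrid(Eg, Fg, indexing="ij")
    D1 = ae.c01 * EE + af.c01 * FF
    D0 = ae.c10 * EE + af.c10 * FF
    if np.all(D0 + D1 == 0):
        raise ZeroActivity("no enzyme activity in either direction")
    denom = (D0 + D1 + (ae.kappa0_tot * D0 + ae.kappa1_tot * D1) * EE
             + (af.kappa0_tot * D0 + af.kappa1_tot * D1) * FF)
    S0g = Stot * D0 / denom
    S1g = Stot * D1 / denom
    G1 = EE * (1 + ae.kappa0_tot * S0g + ae.kappa1_tot * S1g) - Etot
    G2 = FF * (1 + af.kappa0_tot * S0g + af.kappa1_tot * S1g) - Ftot
    R = np.hypot(G1 / scale, G2 / scale)

    # polish candidates: residual-norm local minima plus a coarse lattice of
    # fallback starts (the minima alone can cluster on flat plateaus)
    cand = []
    for i in range(grid):
        for j in range(grid):
            v = R[i, j]
            neigh = R[max(0, i - 1):i + 2, max(0, j - 1):j + 2]
            if v <= neigh.min() + 1e-300:
                cand.append((v, EE[i, j], FF[i, j]))
    cand.sort(key=lambda c: c[0])
    cand = cand[:25]
    step = max(grid // 6, 1)
    for i in range(step // 2, grid, step):
        for j in range(step // 2, grid, step):
            cand.append((R[i, j], EE[i, j], FF[i, j]))

    roots = []
    for _, E0, F0 in cand:
        def fun(z):
            with np.errstate(over="ignore", invalid="ignore"):
                E, F = np.exp(np.clip(z, -700.0, 700.0))
                g1, g2 = resid(E, F)
                return [g1 / scale, g2 / scale]

        sol = _scipy_root(fun, np.log([E0, F0]), method="hybr",
                          options={"xtol": 1e-13})
        # accept by residual, not by status: hybr reports failure when xtol
        # is tighter than the attainable precision even at an exact root
        E, F = np.exp(np.clip(sol.x, -700.0, 700.0))
        if not np.all(np.isfinite([E, F])):
            continue
        g1, g2 = resid(E, F)
        if max(abs(g1), abs(g2)) > residual_tol * scale:
            continue
        if not (0 < E <= Etot * (1 + 1e-9) and 0 < F <= Ftot * (1 + 1e-9)):
            continue
        if any(abs(E - r[0]) <= dedup_tol * max(E, r[0])
               and abs(F - r[1]) <= dedup_tol * max(F, r[1]) for r in roots):
            continue
        roots.append((min(E, Etot), min(F, Ftot)))
    if not roots:
        raise NoRootFound(
            f"no root located; best grid residual {R.min():.3e} "
            f"(E_tot={Etot}, F_tot={Ftot}, S_tot={Stot})")
    roots.sort()
    return [_full_state(cycle, ae, af, E, F) for E, F in roots]


# ---------------------------------------------------------------------------
# full mass-action ODE oracle
# ---------------------------------------------------------------------------

def _assemble_network(cycle: ModificationCycle):
    """Species list and rate-evaluating callable for the full network."""
    species = ([cycle.forward.enzyme, cycle.reverse.enzyme]
               + list(cycle.forward.intermediates)
               + list(cycle.reverse.intermediates) + ["S0", "S1"])
    idx = {s: i for i, s in enumerate(species)}
    terms = []  # (rate_const, multiplier_indices, delta_vector)
    for mech in (cycle.forward, cycle.reverse):
        for rx in mech.reactions:
            k = mech.parameters[rx.rate]
            delta = np.zeros(len(species))
            if rx.kind == "binding":
                mult = (idx[rx.source], idx[rx.substrate])
                delta[idx[rx.source]] -= 1
                delta[idx[rx.substrate]] -= 1
                delta[idx[rx.target]] += 1
            elif rx.kind == "conversion":
                mult = (idx[rx.source],)
                delta[idx[rx.source]] -= 1
                delta[idx[rx.target]] += 1
            else:
                mult = (idx[rx.source],)
                delta[idx[rx.source]] -= 1
                delta[idx[rx.target]] += 1
                delta[idx[rx.substrate]] += 1
            terms.append((k, mult, delta))
    D = np.array([t[2] for t in terms])

    def rhs(t, u):
        rates = np.array([k * np.prod(u[list(m)]) for k, m, _ in terms])
        return rates @ D

    return species, idx, rhs


def ode_oracle(cycle: ModificationCycle, t_end: float = 1e7,
               tol: float = 1e-10, u0: dict | None = None) -> CycleState:
    """Steady state of the full mass-action network by stiff integration.

    Default initial condition: all substrate as S0, all enzyme free.
    Integrates in doubling windows until the infinity norm of du/dt drops
    below ``tol`` times the concentration scale; raises
    :class:`NotConverged` if ``t_end`` is exceeded.
    """
    species, idx, rhs = _assemble_network(cycle)
    u = np.zeros(len(species))
    u[idx[cycle.forward.enzyme]] = cycle.E_tot
    u[idx[cycle.reverse.enzyme]] = cycle.F_tot
    u[idx["S0"]] = cycle.S_tot
    if u0:
        for k, v in u0.items():
            u[idx[k]] = v
    scale = max(cycle.E_tot, cycle.F_tot, cycle.S_tot, 1e-30)
    t, window = 0.0, 1.0
    while t < t_end:
        sol = solve_ivp(rhs, (0.0, window), u, method="LSODA",
                        rtol=1e-10, atol=1e-12 * scale)
        if not sol.success:  # pragma: no cover
            raise NotConverged(f"integration failed: {sol.message}")
        u = sol.y[:, -1]
        t += window
        window *= 2.0
        if np.max(np.abs(rhs(0.0, u))) < tol * scale:
            inter = {y: u[idx[y]] for y in (list(cycle.forward.intermediates)
                                            + list(cycle.reverse.intermediates))}
            return CycleState(E_free=u[idx[cycle.forward.enzyme]],
                              F_free=u[idx[cycle.reverse.enzyme]],
                              S0=u[idx["S0"]], S1=u[idx["S1"]],
                              intermediates=inter)
    raise NotConverged(f"no steady state reached by t = {t_end}")


# ---------------------------------------------------------------------------
# canonical mechanisms
# ---------------------------------------------------------------------------

def mm_mechanism(enzyme: str, kon: float, koff: float, kcat: float,
                 substrate: str = "S0", product: str = "S1",
                 prefix: str | None = None) -> EnzymeMechanism:
    """Classical (strongly irreversible) Michaelis-Menten scheme
    X + S -> Y -> X + P with substrate rebinding only."""
    p = prefix or enzyme.lower()
    y = f"Y{p}"
    return EnzymeMechanism(
        enzyme=enzyme, intermediates=[y],
        reactions=[
            Reaction("binding", enzyme, y, f"{p}_on", substrate),
            Reaction("release", y, enzyme, f"{p}_off", substrate),
            Reaction("release", y, enzyme, f"{p}_cat", product),
        ],
        parameters={f"{p}_on": kon, f"{p}_off": koff, f"{p}_cat": kcat})


def reversible_mm_mechanism(enzyme: str, kon: float, koff: float, kcat: float,
                            krebind: float, kback: float = 0.0,
                            substrate: str = "S0", product: str = "S1",
                            prefix: str | None = None) -> EnzymeMechanism:
    """Two-intermediate mechanism with product rebinding.

    The substrate complex Y can release either substrate or product; the
    product complex Z is reached by product rebinding.  With kback = 0, Z
    can only re-release product, so the enzyme is weakly irreversible
    (product rebinds but is never converted back); kback > 0 adds the
    Z -> Y conversion and makes it fully reversible.
    """
    p = prefix or enzyme.lower()
    y, z = f"Y{p}", f"Z{p}"
    reactions = [
        Reaction("binding", enzyme, y, f"{p}_on", substrate),
        Reaction("release", y, enzyme, f"{p}_off", substrate),
        Reaction("release", y, enzyme, f"{p}_cat", product),
        Reaction("binding", enzyme, z, f"{p}_re", product),
        Reaction("release", z, enzyme, f"{p}_unre", product),
    ]
    params = {f"{p}_on": kon, f"{p}_off": koff, f"{p}_cat": kcat,
              f"{p}_re": krebind, f"{p}_unre": max(koff, 1e-2)}
    if kback > 0:
        reactions.append(Reaction("conversion", z, y, f"{p}_back"))
        params[f"{p}_back"] = kback
    return EnzymeMechanism(enzyme, [y, z], reactions, params)


def random_order_bibi_mechanism(enzyme: str, rates: dict | None = None,
                                prefix: str | None = None,
                                weakly_irreversible: bool = False) -> EnzymeMechanism:
    """Random-order bi-bi-like mechanism: two binding routes for the
    substrate, a central catalytic step, two release routes for the product
    (cofactors absorbed into the rates).

    States: X, Y1, Y2 (substrate-bound), Y3, Y4 (product-bound).
    ``weakly_irreversible=True`` removes the reverse catalytic step.
    """
    p = prefix or enzyme.lower()
    Y = [f"Y1{p}", f"Y2{p}", f"Y3{p}", f"Y4{p}"]
    names = [f"{p}_{i}" for i in range(1, 15)]
    reactions = [
        Reaction("binding", enzyme, Y[0], names[0], "S0"),
        Reaction("binding", enzyme, Y[1], names[1], "S0"),
        Reaction("release", Y[0], enzyme, names[2], "S0"),
        Reaction("release", Y[1], enzyme, names[3], "S0"),
        Reaction("conversion", Y[0], Y[1], names[4]),
        Reaction("conversion", Y[1], Y[0], names[5]),
        Reaction("conversion", Y[0], Y[2], names[6]),       # catalytic step
        Reaction("release", Y[2], enzyme, names[8], "S1"),
        Reaction("release", Y[3], enzyme, names[9], "S1"),
        Reaction("binding", enzyme, Y[2], names[10], "S1"),
        Reaction("binding", enzyme, Y[3], names[11], "S1"),
        Reaction("conversion", Y[2], Y[3], names[12]),
        Reaction("conversion", Y[3], Y[2], names[13]),
    ]
    if not weakly_irreversible:
        reactions.append(Reaction("conversion", Y[2], Y[0], names[7]))
    used = {rx.rate for rx in reactions}
    params = {nm: (rates or {}).get(nm, 1.0) for nm in names if nm in used}
    return EnzymeMechanism(enzyme, Y, reactions, params)


def deadend_phosphatase_mechanism(enzyme: str, rates: dict | None = None,
                                  prefix: str | None = None,
                                  weakly_irreversible: bool = False) -> EnzymeMechanism:
    """Single-route hydrolase-like mechanism with a dead-end complex.

    States: X, Y5 (product-of-cycle-bound), Y6 (substrate-bound), Y7
    (dead-end).  Converts S1 -> S0 (the reverse leg of a cycle).  The
    dead-end complex only sequesters enzyme: it contributes to the rgMMCs
    but to neither tgCE.
    """
    p = prefix or enzyme.lower()
    Y = [f"Y5{p}", f"Y6{p}", f"Y7{p}"]
    names = [f"{p}_{i}" for i in range(1, 10)]
    reactions = [
        Reaction("binding", enzyme, Y[0], names[0], "S1"),
        Reaction("release", Y[0], enzyme, names[1], "S1"),
        Reaction("conversion", Y[0], Y[1], names[2]),       # catalytic step
        Reaction("release", Y[1], enzyme, names[4], "S0"),
        Reaction("binding", enzyme, Y[1], names[5], "S0"),
        Reaction("binding", enzyme, Y[2], names[6], "S1"),  # dead end
        Reaction("release", Y[2], enzyme, names[7], "S1"),
    ]
    if not weakly_irreversible:
        reactions.append(Reaction("conversion", Y[1], Y[0], names[3]))
    used = {rx.rate for rx in reactions}
    params = {nm: (rates or {}).get(nm, 1.0) for nm in names if nm in used}
    return EnzymeMechanism(enzyme, Y, reactions, params)


def random_cycle(seed: int = 0, r: float = 1.0) -> ModificationCycle:
    """Random modification cycle for round-trip validation.

    Mechanism families for each leg are drawn from {strongly irreversible
    MM, weakly irreversible single-intermediate, fully reversible
    single-intermediate, random-order bi-bi-like, dead-end hydrolase-like};
    rates log-uniform in [10^-r, 10^r]; totals log-uniform in [0.3, 3].
    """
    rng = np.random.default_rng(seed)

    def draw():
        return float(10.0 ** rng.uniform(-r, r))

    def pick_forward(enzyme, prefix):
        fam = rng.integers(4)
        if fam == 0:
            return mm_mechanism(enzyme, draw(), draw(), draw(), prefix=prefix)
        if fam == 1:
            return reversible_mm_mechanism(enzyme, draw(), draw(), draw(),
                                           draw(), 0.0, prefix=prefix)
        if fam == 2:
            return reversible_mm_mechanism(enzyme, draw(), draw(), draw(),
                                           draw(), draw(), prefix=prefix)
        m = random_order_bibi_mechanism(enzyme, prefix=prefix,
                                        weakly_irreversible=bool(rng.integers(2)))
        m.parameters = {k: draw() for k in m.parameters}
        return m

    def pick_reverse(enzyme, prefix):
        fam = rng.integers(4)
        if fam == 0:
            return mm_mechanism(enzyme, draw(), draw(), draw(),
                                substrate="S1", product="S0", prefix=prefix)
        if fam == 1:
            return reversible_mm_mechanism(enzyme, draw(), draw(), draw(),
                                           draw(), 0.0, substrate="S1",
                                           product="S0", prefix=prefix)
        if fam == 2:
            return reversible_mm_mechanism(enzyme, draw(), draw(), draw(),
                                           draw(), draw(), substrate="S1",
                                           product="S0", prefix=prefix)
        m = deadend_phosphatase_mechanism(enzyme, prefix=prefix,
                                          weakly_irreversible=bool(rng.integers(2)))
        m.parameters = {k: draw() for k in m.parameters}
        return m

    fwd = pick_forward("E", "e")
    rev = pick_reverse("F", "f")
    totals = 10.0 ** rng.uniform(np.log10(0.3), np.log10(3.0), size=3)
    return ModificationCycle(forward=fwd, reverse=rev,
                             E_tot=float(totals[0]), F_tot=float(totals[1]),
                             S_tot=float(totals[2]))
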