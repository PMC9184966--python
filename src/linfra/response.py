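"""Input-output response functions and sharpness (position-steepness) analysis.

An output is a non-negative linear combination of steady-state probabilities,
f(x) = sum_i lambda_i u_i*(x), with x the concentration of an input ligand.
f is a bounded rational function on [0, inf).  Sharpness is measured
intrinsically: normalise the input by the half-max point x0.5 (the smallest
positive x where f is halfway between its global min m and max M over
[0, inf)), set g(y) = f(y*x0.5), and define

    s = max over y >= 0 of |dg/dy|   (steepness)
    p = the y attaining that maximum (position).

The Hill functions H_h(x) = x^h / (1 + x^h) serve as the reference family:
their (p, s) locus (the Hill line) has the closed form
p = ((h-1)/(h+1))^(1/h).  The Hill function H_m is the empirical sharpness
bound (Hopfield barrier) for equilibrium mechanisms in which the input binds
at m sites; exceeding it requires energy expenditure.

All maximisation is exact for rational f: critical points are polynomial
roots, with the y = 0 endpoint included and ties broken toward smaller y.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import sympy as sp

from .errors import ConstantFunction, NoInputSymbol, NotStronglyConnected
from .graph import LFGraph, is_strongly_connected
from .mtt import rho

__all__ = ["OutputSpec", "ResponseFunction", "HillFunction",
           "response_function", "response_function_symbolic",
           "half_max_point", "position_steepness", "hill_ps", "hill_line",
           "sample_ps_region", "PSPoint"]

_ROOT_IMAG_TOL = 1e-9


@dataclass(frozen=True)
class PSPoint:
    position: float
    steepness: float
    degenerate: bool = False  # p below the anomalous-boundary cutoff


@dataclass
class OutputSpec:
    """Non-negative output coefficients, one per vertex, not all zero."""
    coefficients: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.coefficients, dtype=float)
        if np.any(c < 0) or not np.any(c > 0):
            raise ValueError("coefficients must be non-negative, not all zero")
        self.coefficients = c


class ResponseFunction:
    """Bounded rational function of x >= 0, as coefficient arrays.

    ``num`` and ``den`` are ascending-power coefficient arrays; boundedness
    requires deg(num) <= deg(den) and a denominator positive on [0, inf).
    """

    def __init__(self, num, den):
        num = np.trim_zeros(np.asarray(num, dtype=float), "b")
        den = np.trim_zeros(np.asarray(den, dtype=float), "b")
        if den.size == 0:
            raise ZeroDivisionError("zero denominator")
        if num.size == 0:
            num = np.zeros(1)
        if num.size > den.size:
            raise ValueError("response must be bounded: deg(num) <= deg(den)")
        # common scale is irrelevant to the ratio; normalising keeps the
        # coefficients of exact-rational pipelines at order one
        scale = np.max(np.abs(den))
        self.num = num / scale
        self.den = den / scale

    @classmethod
    def from_expr(cls, expr: sp.Expr, x: sp.Symbol) -> "ResponseFunction":
        n, d = sp.fraction(sp.cancel(sp.together(expr)))
        pn = sp.Poly(n, x)
        pd = sp.Poly(d, x)
        return cls([float(c) for c in pn.all_coeffs()[::-1]],
                   [float(c) for c in pd.all_coeffs()[::-1]])

    @property
    def degree(self) -> int:
        return max(self.num.size, self.den.size) - 1

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        return (np.polynomial.polynomial.polyval(x, self.num)
                / np.polynomial.polynomial.polyval(x, self.den))

    def limit_at_infinity(self) -> float:
        if self.num.size < self.den.size:
            return 0.0
        return self.num[-1] / self.den[-1]

    # -- calculus helpers --------------------------------------------------
    def _dnum(self):
        """Ascending coefficients of the numerator of f' (i.e. n'd - nd')."""
        P = np.polynomial.polynomial
        n, d = self.num, self.den
        q = P.polysub(P.polymul(P.polyder(n), d), P.polymul(n, P.polyder(d)))
        return np.trim_zeros(q, "b")

    def is_constant(self, tol: float = 0.0) -> bool:
        q = self._dnum()
        return q.size == 0 or np.all(q == 0)

    def extrema(self):
        """(m, M): global min and max of f over [0, inf)."""
        q = self._dnum()
        cands = [0.0]
        if q.size > 1:
            roots = np.polynomial.polynomial.polyroots(q)
            cands += [r.real for r in roots
                      if abs(r.imag) <= _ROOT_IMAG_TOL * max(1, abs(r))
                      and r.real > 0]
        vals = [float(self(c)) for c in cands] + [self.limit_at_infinity()]
        return min(vals), max(vals)


def _positive_real_roots(coeffs) -> np.ndarray:
    coeffs = np.trim_zeros(np.asarray(coeffs, dtype=float), "b")
    if coeffs.size <= 1:
        return np.array([])
    roots = np.polynomial.polynomial.polyroots(coeffs)
    out = [r.real for r in roots
           if abs(r.imag) <= _ROOT_IMAG_TOL * max(1.0, abs(r)) and r.real > 0]
    return np.sort(np.array(out))


@dataclass(frozen=True)
class HillFunction:
    """H_h(x) = x^h / (1 + x^h); x0.5 = 1 for every h > 0."""
    h: float

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        xh = np.power(x, self.h)
        return xh / (1.0 + xh)

    def derivative(self, y):
        y = np.asarray(y, dtype=float)
        yh = np.power(y, self.h)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = self.h * np.power(y, self.h - 1.0) / (1.0 + yh) ** 2
        return out

    def as_response(self) -> ResponseFunction:
        h = int(round(self.h))
        if abs(h - self.h) > 1e-12 or h < 1:
            raise ValueError("only integer h >= 1 has a rational representation")
        num = np.zeros(h + 1)
        num[h] = 1.0
        den = np.zeros(h + 1)
        den[0] = 1.0
        den[h] = 1.0
        return ResponseFunction(num, den)


def response_function_symbolic(g: LFGraph, output) -> sp.Expr:
    """Exact symbolic response sum_i lambda_i u_i* as a cancelled rational
    function of all the graph's symbols (parameters left symbolic)."""
    if g.input_symbol is None:
        raise NoInputSymbol("graph has no designated input symbol")
    lam = output.coefficients if isinstance(output, OutputSpec) else np.asarray(output, float)
    rs = rho(g)
    numer = sp.Add(*[sp.nsimplify(lam[i]) * rs[i] for i in range(g.n) if lam[i]])
    denom = sp.Add(*rs)
    return sp.cancel(numer / denom)


def response_function(g: LFGraph, output) -> ResponseFunction:
    """Response function with parameters bound numerically; exact in x.

    Uses the symbolic Matrix-Tree sum with parameter values substituted, so
    the returned rational function is the true steady-state output with
    common polynomial factors cancelled.
    """
    if g.input_symbol is None:
        raise NoInputSymbol("graph has no designated input symbol")
    if not is_strongly_connected(g):
        raise NotStronglyConnected("response needs a strongly connected graph")
    x = sp.Symbol(g.input_symbol)
    lam = output.coefficients if isinstance(output, OutputSpec) else np.asarray(output, float)
    # exact rational substitution: floats are binary rationals, so common
    # polynomial factors (e.g. under an exactly-imposed cycle condition)
    # cancel exactly instead of surviving as round-off
    subs = {k: (sp.Rational(v) if isinstance(v, float) else sp.nsimplify(v))
            for k, v in g.substitutions().items() if k != x}
    rs = [r.xreplace(subs) for r in rho(g, expand=True)]
    missing = set().union(*[r.free_symbols for r in rs]) - {x}
    if missing:
        from .errors import UnboundParameter
        raise UnboundParameter(missing)
    numer = sp.expand(sp.Add(*[sp.Rational(float(lam[i])) * rs[i]
                               for i in range(g.n) if lam[i]]))
    denom = sp.expand(sp.Add(*rs))
    return ResponseFunction.from_expr(numer / denom, x)


def half_max_point(f: ResponseFunction) -> float:
    """Smallest positive x with f(x) = (m + M)/2."""
    if f.is_constant():
        raise ConstantFunction("x0.5 undefined for a constant response")
    m, M = f.extrema()
    c = 0.5 * (m + M)
    P = np.polynomial.polynomial
    coeffs = P.polysub(f.num, c * np.asarray(f.den))
    roots = _positive_real_roots(coeffs)
    if roots.size == 0:
        raise ConstantFunction("no positive half-max crossing found")
    return float(roots[0])


def position_steepness(f: ResponseFunction) -> PSPoint:
    """Global maximisation of |g'| for g(y) = f(y * x0.5).

    Critical points are the positive real roots of the numerator of f''
    (exact for rational f); the y = 0 endpoint is always a candidate and
    ties break toward smaller y.
    """
    if f.is_constant():
        raise ConstantFunction("sharpness undefined for a constant response")
    x05 = half_max_point(f)
    P = np.polynomial.polynomial
    q = f._dnum()                      # numerator of f'
    d = f.den
    # numerator of f'' = q' d - 2 q d'
    q2 = P.polysub(P.polymul(P.polyder(q), d), 2.0 * P.polymul(q, P.polyder(d)))
    cands = np.concatenate([[0.0], _positive_real_roots(q2)])

    def absdg(xv):
        return abs(x05 * P.polyval(xv, q) / P.polyval(xv, d) ** 2)

    best_y, best_s = None, -np.inf
    for xv in sorted(cands):
        s = absdg(xv)
        # strict improvement required: candidates come smallest-y first, so
        # ties resolve to the smaller y automatically
        if best_y is None or s > best_s * (1 + 1e-12) + 1e-300:
            best_s, best_y = s, xv / x05
    return PSPoint(position=float(best_y), steepness=float(best_s),
                   degenerate=best_y < 0.05)


def hill_ps(h: float) -> PSPoint:
    """Closed-form (p, s) of the Hill function H_h (h >= 1)."""
    if h < 1:
        raise ValueError("h < 1 has unbounded derivative at 0")
    if h == 1:
        return PSPoint(0.0, 1.0, degenerate=True)
    p = ((h - 1.0) / (h + 1.0)) ** (1.0 / h)
    s = float(HillFunction(h).derivative(p))
    return PSPoint(position=p, steepness=s, degenerate=p < 0.05)


def hill_line(h_values) -> list[PSPoint]:
    """The Hill line: (p, s) locus of the Hill functions, h > 1."""
    out = []
    for h in h_values:
        if h <= 1:
            raise ValueError("hill_line is defined for h > 1")
        out.append(hill_ps(float(h)))
    return out


# ---------------------------------------------------------------------------
# (p, s) region sampling
# ---------------------------------------------------------------------------

@dataclass
class PSRegionSample:
    points: list          # list of PSPoint
    seed: int
    mode: str
    family: str
    m: int
    log_range: float
    hull: np.ndarray | None = None   # convex hull vertices of (p, s) cloud
    draws: list = field(default_factory=list)

    @property
    def p(self) -> np.ndarray:
        return np.array([pt.position for pt in self.points])

    @property
    def s(self) -> np.ndarray:
        return np.array([pt.steepness for pt in self.points])

    def max_steepness(self, p_min: float = 0.05) -> float:
        mask = self.p >= p_min
        return float(np.max(self.s[mask])) if np.any(mask) else 0.0

    def beyond_barrier(self, h: float, tol: float = 1e-3) -> np.ndarray:
        """Indices of points lying above-and-to-the-right of the (p, s) of
        the Hill function H_h — the signature of non-equilibrium behaviour
        when h is the number of input binding sites.

        Near the anomalous p -> 0 boundary steepness is unbounded even at
        equilibrium, so only joint excess in both coordinates counts.
        """
        ref = hill_ps(h)
        mask = (self.p >= ref.position + tol) & (self.s >= ref.steepness + tol)
        return np.nonzero(mask)[0]


def _hypercube_patterns(n_sites: int):
    """All binding patterns of n_sites sites, reference (all unbound) first."""
    return [tuple((v >> k) & 1 for k in range(n_sites)) for v in range(2 ** n_sites)]


def _equilibrium_hypercube_response(rng, m: int, r: float):
    """One equilibrium draw of the regulated-recruitment model on C(m+1).

    Sites 0..m-1 bind the input ligand; site m binds the polymerase.  At
    equilibrium the steady state is Boltzmann, so a draw is a set of vertex
    weights K_v (log-uniform in [10^-r, 10^r], reference vertex weight 1);
    mu_v(x) = K_v * x^(#input sites bound), giving numerator/denominator
    polynomials in x of degree <= m.
    """
    pats = _hypercube_patterns(m + 1)
    K = 10.0 ** rng.uniform(-r, r, size=len(pats))
    K[0] = 1.0
    num = np.zeros(m + 1)
    den = np.zeros(m + 1)
    for K_v, pat in zip(K, pats):
        b = sum(pat[:m])
        den[b] += K_v
        if pat[m]:                      # polymerase bound -> output vertex
            num[b] += K_v
    return num, den, K


def sample_ps_region(family: str = "hypercube", m: int = 2,
                     n_samples: int = 1000, seed: int = 0,
                     mode: str = "equilibrium", log_range: float = 3.0,
                     graph: LFGraph | None = None, output=None,
                     keep_draws: bool = False) -> PSRegionSample:
    """Monte-Carlo sample of the (p, s) region of a model family.

    family='hypercube' is the regulated-recruitment model on C(m+1) (input
    bound at m sites, output = polymerase-site occupancy).  Equilibrium mode
    draws Boltzmann vertex weights (which always satisfy the cycle
    condition); non-equilibrium mode draws every edge label independently
    and uses the Matrix-Tree sum, which is feasible only for small m.
    family='graph' samples log-uniform parameters on a user graph + output.

    This is plain Monte-Carlo sampling with a convex-hull summary — no
    incremental boundary-growing is attempted.  Identical seeds give
    identical clouds.
    """
    rng = np.random.default_rng(seed)
    points, draws = [], []

    if family == "hypercube" and mode == "equilibrium":
        for _ in range(n_samples):
            num, den, K = _equilibrium_hypercube_response(rng, m, log_range)
            f = ResponseFunction(num, den)
            points.append(position_steepness(f))
            if keep_draws:
                draws.append(K)
    elif family == "hypercube":
        from .fixtures import make_hypercube
        base = make_hypercube(m + 1, input_sites=range(m))
        syms = sorted(base.free_symbols() - {sp.Symbol(base.input_symbol)},
                      key=str)
        out_coeffs = np.array([float(base.annotations[v][m]) for v in base.vertices])
        for _ in range(n_samples):
            vals = {str(sym): 10.0 ** rng.uniform(-log_range, log_range)
                    for sym in syms}
            gi = base.with_parameters(**vals)
            f = response_function(gi, out_coeffs)
            points.append(position_steepness(f))
            if keep_draws:
                draws.append(vals)
    elif family == "graph":
        if graph is None or output is None:
            raise ValueError("family='graph' requires graph and output")
        x = sp.Symbol(graph.input_symbol) if graph.input_symbol else None
        syms = sorted(graph.free_symbols() - ({x} if x else set()), key=str)
        for _ in range(n_samples):
            vals = {str(sym): 10.0 ** rng.uniform(-log_range, log_range)
                    for sym in syms}
            if mode == "equilibrium":
                raise ValueError("equilibrium sampling on a custom graph is "
                                 "not supported; use a detailed-balanced "
                                 "fixture or the hypercube family")
            gi = graph.with_parameters(**vals)
            f = response_function(gi, output)
            points.append(position_steepness(f))
            if keep_draws:
                draws.append(vals)
    else:
        raise ValueError(f"unknown family {family!r}")

    hull = None
    pts = np.array([[pt.position, pt.steepness] for pt in points])
    if len(points) >= 3 and np.ptp(pts, axis=0).min() > 0:
        try:
            from scipy.spatial import ConvexHull
            hull = pts[ConvexHull(pts).vertices]
        except Exception:      # collinear clouds etc.
            hull = None
    return PSRegionSample(points=points, seed=seed, mode=mode, family=family,
                          m=m, log_range=log_range, hull=hull, draws=draws)
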