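# Methods

`linfra` analyses finite, simple, directed graphs whose edges carry positive
rate labels. Such a graph G generates a linear dynamics du/dt = L(G)·u on
vertex concentrations (or state probabilities), with L(G) the
column-sum-zero Laplacian: L[j,i] = ℓ(i→j) off the diagonal and diagonals
chosen so each column sums to zero. Column-sum zero encodes conservation of
total material u_tot. This one convention is fixed package-wide; no row-sum
or transposed variants are offered, to eliminate a classic source of silent
transposition bugs.

## Labels and the label grammar

Labels are rates (time⁻¹); bimolecular steps carry a concentration symbol as
a factor (e.g. `kon*x` for ligand binding). The label grammar is restricted
to symbols, positive numbers, `+`, `*` and parentheses. Subtraction and
division are rejected at parse time, which makes strict positivity of every
label under positive parameter assignments a *syntactic* guarantee rather
than a runtime check. Quantities that genuinely require ratios — Michaelis
constants, catalytic efficiencies — are aggregated parameters computed *from*
graphs, never labels *on* graphs.

## Steady states via spanning trees

For strongly connected G the kernel of L(G) is one-dimensional, and the
Matrix-Tree theorem gives its canonical positive basis vector:
ρ_i(G) = Σ_{T rooted at i} Π_{edges of T} ℓ, a sum over directed spanning
trees. The steady state is u*_i = ρ_i/(Σ_j ρ_j)·u_tot.

Enumeration assigns each non-root vertex one outgoing edge and backtracks on
cycles; since a forest is exactly such an assignment, each forest is
produced once, with no deduplication pass. An all-edge-subsets filter
remains in the test suite as an independent oracle for graphs with ≤ 5
vertices. Tree *counts* use the principal minor of the unit-label Laplacian
in exact integer arithmetic (sympy's fraction-free Berkowitz determinant),
so even the 16-vertex binding hypercube's count (42 467 328) is exact.

Numeric steady states bypass enumeration: delete the reference vertex's row
and column of L and solve the resulting nonsingular system for the scaled
kernel vector, falling back to an SVD nullspace when the condition number
exceeds 10¹². The reference vertex defaults to the first declared vertex.

`propagate` integrates the linear dynamics with BDF (the exact constant
Jacobian is supplied), rtol 1e-8 / atol 1e-10. Defaults elsewhere: relative
tolerance 1e-9 wherever a tolerance is not otherwise stated, overridable per
call.

## Thermodynamics

A reversible graph can reach thermodynamic equilibrium iff the product of
label ratios around every cycle of reversible edges is 1 (the
cycle/Wegscheider condition). The check uses the fundamental cycles of one
spanning tree of the undirected support and a tolerance on |ln μ(C)| (log
scale makes it direction-symmetric); the default 1e-9 is a package choice —
no canonical tolerance exists for numeric labels. When the condition holds,
μ_i (the path product from the reference vertex) gives Boltzmann-factor
weights and the equilibrium steady state u*_i = μ_i/Σμ_j; only label
*ratios* enter, which a regression test pins by rescaling edge pairs.
Accumulation is done in log space, and a ratio spread beyond 10¹² triggers a
conditioning warning rather than an error.

The log label ratio ln(ℓ(i→j)/ℓ(j→i)) is reported as the total entropy
change of the transition in units of k_B. No temperature parameter is
introduced and no environment/internal decomposition is attempted.

Free-ligand closure: with the input symbol read as free ligand [L], the
conservation law L_tot = [L] + Σ_{L-bound i} u*_i([L]) has a unique root
because the left-minus-right residual is strictly increasing in [L]; Brent
bracketing on (0, L_tot] finds it.

## Coarse graining

Given a partition of the vertices of a strongly connected reversible graph,
the quotient graph takes an edge w→z whenever any member edge crosses, with
label Q·Σ_{j∈block z} ρ_j(G). With this labelling the quotient always
satisfies the cycle condition — even when the fine graph does not — and its
steady state aggregates the fine one exactly. Q (default 1) fixes dimensions
only and cancels at steady state; tests verify invariance over six orders of
magnitude. The construction is steady-state-only: a regression test
documents a fixture where the coarse dynamics diverges from the aggregated
fine dynamics at finite time.

Labels are evaluated numerically (per input value); no symbolic coarse
labels are stored, since ρ-polynomials on large graphs are enormous while
all downstream consumers need only values.

Output pushforward at equilibrium uses the constructive coefficients
λ_w = (Σ_{i∈w} λ_i μ_i)/(Σ_{i∈w} μ_i), evaluated at a reference input. The
theory asserts existence of input-independent coefficients without giving a
formula; this choice is the μ-weighted block average, and tests verify input
independence at 20 points across six decades.

## Sharpness (position–steepness)

An output f(x) = Σ λ_i u*_i(x), λ_i ≥ 0, is a bounded rational function of
the input on [0, ∞). Let M, m be its global extrema there and x₀.₅ the
smallest positive x with f = (M+m)/2. For g(y) = f(y·x₀.₅):

* steepness s = max_{y≥0} |g′(y)|, position p = argmax.

For rational f all of this is exact polynomial algebra: extrema candidates
are the positive real roots of the numerator of f′ plus y = 0 and the
x → ∞ limit; |g′| maximisation uses the roots of the numerator of f″. Ties
break toward smaller y, consistent with the "smallest positive" convention
for x₀.₅. A 10⁶-point log-grid maximiser is kept as a test oracle.

Hill references H_h(x) = x^h/(1+x^h) have the closed form
p(h) = ((h−1)/(h+1))^(1/h) (from d ln g′/dy = 0), with s(h) = g′(p(h));
h = 1 sits on the degenerate boundary (p = 0, s = 1) and h < 1 is rejected.

Exact cancellation: `response_function` substitutes parameters as exact
binary rationals before cancelling, so a response whose parameters satisfy
the cycle condition exactly collapses to its true lower degree (the
four-state worked example drops from degree 2 to 1) instead of retaining
round-off-sized spurious coefficients.

### (p, s) region sampling

Equilibrium sampling of the regulated-recruitment model (hypercube C_{m+1}:
m input-ligand sites plus one polymerase site, output = polymerase-site
occupancy) uses the Boltzmann parametrization: at equilibrium the steady
state depends only on vertex weights, so a draw is one log-uniform weight
per binding pattern (range 10^±r, r = 3 by default — the sampled range is a
package choice, configurable). Then μ_v(x) = K_v·x^(#input sites bound),
and the response is a ratio of degree-≤ m polynomials assembled directly —
no tree enumeration — which is what makes 10⁴ draws of the 32-vertex
five-site model take seconds. A test confirms the same construction,
realised as an explicit graph with labels s_ij·e^((φ_i−φ_j)/2), passes the
cycle condition.

Sampling is plain Monte-Carlo with a convex-hull summary; no incremental
boundary-growing is attempted. Points with p < 0.05 are flagged degenerate,
not discarded: steepness is unbounded as p → 0 *even at equilibrium* (a
legitimate five-site equilibrium draw with p ≈ 0.07 reaches s ≈ 1.44, above
s(H₄) ≈ 1.065 — verified against the grid oracle). The empirical
Hopfield-barrier check is therefore stated jointly: no equilibrium sample
lies above *and* to the right of (p(H_m), s(H_m)). Exceeding the barrier
point in both coordinates at once is the signature of energy expenditure;
tests assert its absence over 10⁴ seeded draws for m = 4.

## Enzyme mechanisms and the modification cycle

Mechanisms are built from three reaction shapes — binding X+S*→Y_i,
conversion Y_i→Y_j, release Y_k→X+S* — with S* ∈ {S0, S1} and the enzyme
graph required to be strongly connected. Substrate symbols appear only on
edges leaving the free enzyme (the uncoupling condition), so the Matrix-Tree
vector is constant at X and homogeneous linear in [S0], [S1] at every
intermediate; `aggregated_params` asserts both properties rather than
assuming them. Cofactors (ATP/ADP) are absorbed into rate constants.

The aggregated parameters are: rgMMCs κ_{b,Y} (coefficients of [S_b] in
ρ_Y/ρ_X — generalised reciprocal Michaelis constants), their totals
(trgMMCs), and catalytic efficiencies computed as sums over product-release
edges of rate × matching rgMMC. The release-weighted-sum rule is stated in
the source literature only for one worked mechanism; the general rule used
here is validated against the full mass-action ODE on random mechanisms.
Classification is direction-aware: with product P, κ_P = 0 means strongly
irreversible (product cannot rebind); κ_P > 0 with zero reverse efficiency
means weakly irreversible. Dead-end complexes contribute to κ
(sequestration) but to no efficiency.

For a two-enzyme cycle the substrate ratio [S1]*/[S0]* equals
(c01E·E + c01F·F)/(c10E·E + c10F·F) in the free enzyme concentrations, and
substrate conservation closes the system. The closure is kept homogeneous
(S0 ∝ D0, S1 ∝ D1), so fully/weakly irreversible limits with D0 = 0 need no
special-casing; `ZeroActivity` is raised only when both directions are dead.
The two enzyme conservation equations E_tot = R_E(E,F), F_tot = R_F(E,F)
are solved on (0,E_tot]×(0,F_tot] by a 200×200 log-grid residual scan whose
local minima (plus a coarse fallback lattice) seed Powell-hybrid polishing
in log coordinates; acceptance is by residual, not solver status, because
MINPACK reports failure at an exact root when xtol is below attainable
precision. Roots deduplicate at 1e-6 relative, and every root
back-substitutes to the complete state, which satisfies all three
conservation laws by construction.

The independent oracle integrates the full mass-action network (LSODA,
doubling time windows) to ‖du/dt‖∞ < 1e-10·scale. Scope is deliberately the
two-enzyme, one-substrate binary cycle: mechanism lists keep the
architecture open for multisite systems, but only the cycle solver is
implemented and tested.

## Fixtures: what the generators emulate

* `make_hypercube(n)` — ligand binding/unbinding on n sites; 2^n pattern
  vertices, reversible one-bit-flip edges, input symbol on designated
  binding edges, pattern annotations for coarse graining.
* `make_detailed_balanced` — equilibrium parametrizations from vertex
  potentials φ and symmetric edge scales (both log-uniform over 10^±r,
  r = 3): ℓ(i→j) = s_ij·e^((φ_i−φ_j)/2), so the cycle condition holds to
  float rounding and μ_i = e^(φ₁−φ_i) is recoverable.
* `make_allosteric_square` — the four-state conformation/binding square. The
  parameter-to-edge assignment (1→2:k5, 2→1:k1, 1→3:k2·x, 3→1:k8, 2→4:k6·x,
  4→2:k4, 3→4:k3, 4→3:k7; vertices 1,2 unbound, 3,4 bound) is the unique
  one, up to the square's symmetry, under which the single cycle's
  condition reads k1k2k3k4 = k5k6k7k8 and the equilibrium response is
  (k2/k8)(1+k3/k7)·x over (1+k5/k1) + (k2/k8)(1+k3/k7)·x.
* `random_cycle` — modification cycles with legs drawn from five mechanism
  families (strongly irreversible MM, weakly irreversible and fully
  reversible two-intermediate schemes, a five-state two-route mechanism, a
  dead-end-complex hydrolase), rates log-uniform 10^±1, totals in [0.3, 3] —
  moderate scales chosen so stiff integration converges within the test
  budget.

All generators route randomness through a single `numpy` Generator seed.
Synthetic fixtures exercise algebraic identities and solver correctness;
they do not emulate measurement noise, thermal parameter correlations, or
realistic biological rate magnitudes, so a green test establishes
mathematical correctness of the computations, not biological calibration.

## Known limitations

* Spanning-tree enumeration is exponential; counts beyond ~10⁴ trees should
  use the determinant path, and symbolic ρ is intended for graphs of ≤ ~8
  vertices.
* Non-equilibrium (p, s) sampling on hypercubes runs through symbolic ρ and
  is feasible only for small m; characterising those regions is open
  territory, not a package goal.
* Non-strongly-connected graphs, synthesis/degradation extensions,
  stochastic (Gillespie) simulation, first-passage machinery and
  entropy-production decompositions are out of scope.
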