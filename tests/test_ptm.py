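"""Enzyme grammar, aggregated parameters, cycle reduction and the ODE oracle."""

import numpy as np
import pytest
import sympy as sp

from linfra import (EnzymeMechanism, ModificationCycle, Reaction,
                    aggregated_params, mechanism_graph, ode_oracle,
                    reduced_system, solve_cycle, substrate_graph)
from linfra.ptm import (deadend_phosphatase_mechanism, mm_mechanism,
                        random_cycle, random_order_bibi_mechanism,
                        reversible_mm_mechanism)
from linfra.errors import GrammarViolation, NotStronglyConnected
from linfra import mtt


class TestMechanismGraph:
    def test_classical_scheme_two_vertices(self):
        """The classical scheme with product rebinding to the same complex:
        4 reactions merge onto a simple 2-vertex graph."""
        m = EnzymeMechanism("E", ["Y"], [
            Reaction("binding", "E", "Y", "kon", "S0"),
            Reaction("release", "Y", "E", "koff", "S0"),
            Reaction("release", "Y", "E", "kcat", "S1"),
            Reaction("binding", "E", "Y", "kre", "S1")],
            parameters={"kon": 1.0, "koff": 1.0, "kcat": 1.0, "kre": 1.0})
        g = mechanism_graph(m)
        assert g.n == 2 and len(g.edges) == 2   # parallel reactions merged
        lab = g.edges[("E", "Y")]
        assert lab.has(sp.Symbol("S0")) and lab.has(sp.Symbol("S1"))

    def test_bibi_strongly_connected_five_states(self):
        g = mechanism_graph(random_order_bibi_mechanism("E"))
        assert g.n == 5

    def test_substrate_on_conversion_rejected(self):
        with pytest.raises(GrammarViolation):
            EnzymeMechanism("E", ["Y1", "Y2"], [
                Reaction("binding", "E", "Y1", "k1", "S0"),
                Reaction("conversion", "Y1", "Y2", "k2", "S0"),
                Reaction("release", "Y2", "E", "k3", "S1")])

    def test_disconnected_mechanism_rejected(self):
        m = EnzymeMechanism("E", ["Y1", "Y2"], [
            Reaction("binding", "E", "Y1", "k1", "S0"),
            Reaction("release", "Y1", "E", "k2", "S1"),
            Reaction("conversion", "Y1", "Y2", "k3")])  # Y2 is a sink
        with pytest.raises(NotStronglyConnected):
            mechanism_graph(m)


class TestAggregatedParams:
    def test_michaelis_menten_closed_form(self):
        """kappa is the reciprocal Michaelis constant kon/(koff+kcat);
        the catalytic efficiency is kcat*kon/(koff+kcat)."""
        kon, koff, kcat = sp.symbols("e_on e_off e_cat")
        a = aggregated_params(mm_mechanism("E", 1.0, 1.0, 1.0))
        assert sp.simplify(a.kappa0["Ye"] - kon / (koff + kcat)) == 0
        assert a.kappa1_tot == 0
        assert sp.simplify(a.c01 - kcat * kon / (koff + kcat)) == 0
        assert a.c10 == 0

    def test_irreversibility_classification(self):
        strong = aggregated_params(mm_mechanism("E", 2.0, 1.0, 3.0))
        assert strong.is_strongly_irreversible()
        assert not strong.is_weakly_irreversible()
        weak = aggregated_params(
            reversible_mm_mechanism("E", 2.0, 1.0, 3.0, 0.5, kback=0.0))
        assert not weak.is_strongly_irreversible()
        assert weak.is_weakly_irreversible()
        full = aggregated_params(
            reversible_mm_mechanism("E", 2.0, 1.0, 3.0, 0.5, kback=0.7))
        assert not full.is_strongly_irreversible()
        assert not full.is_weakly_irreversible()

    def test_classification_matches_syntax_on_random_mechanisms(self):
        """kappa1 = 0 iff no product-binding route; c10 = 0 iff in addition
        no product-to-substrate conversion path exists."""
        rng = np.random.default_rng(8)
        for i in range(12):
            wi = bool(rng.integers(2))
            m = random_order_bibi_mechanism("E", weakly_irreversible=wi)
            m.parameters = {k: float(10 ** rng.uniform(-1, 1))
                            for k in m.parameters}
            a = aggregated_params(m)
            assert not a.is_strongly_irreversible()   # product always rebinds
            assert a.is_weakly_irreversible() == wi

    def test_tgce_is_release_weighted_sum(self):
        """The forward efficiency decomposes over product-release edges as
        rate x matching rgMMC."""
        m = random_order_bibi_mechanism("E")
        a = aggregated_params(m)
        expect = sp.Integer(0)
        for rx in m.reactions:
            if rx.kind == "release" and rx.substrate == "S1":
                expect += sp.Symbol(rx.rate) * a.kappa0[rx.source]
        assert sp.simplify(a.c01 - expect) == 0

    def test_invariant_under_intermediate_relabelling(self):
        def mech(names):
            y1, y2 = names
            return EnzymeMechanism("E", [y1, y2], [
                Reaction("binding", "E", y1, "k1", "S0"),
                Reaction("release", y1, "E", "k2", "S0"),
                Reaction("conversion", y1, y2, "k3"),
                Reaction("conversion", y2, y1, "k4"),
                Reaction("release", y2, "E", "k5", "S1"),
                Reaction("binding", "E", y2, "k6", "S1")],
                parameters={f"k{i}": float(i) for i in range(1, 7)})
        a1 = aggregated_params(mech(["Ya", "Yb"]))
        a2 = aggregated_params(mech(["Q7", "Q3"]))
        assert sp.simplify(a1.c01 - a2.c01) == 0
        assert sp.simplify(a1.kappa0_tot - a2.kappa0_tot) == 0

    def test_deadend_contributes_to_kappa_not_c(self):
        m = deadend_phosphatase_mechanism("F")
        a = aggregated_params(m)
        dead = "Y7f"
        assert sp.simplify(a.kappa1[dead]) != 0      # sequesters enzyme
        assert not a.c01.has(sp.Symbol("f_7"))       # dead-end rates absent
        assert not a.c10.has(sp.Symbol("f_7"))


class TestSubstrateGraph:
    def _cycle(self, **kw):
        fwd = mm_mechanism("E", 2.0, 1.0, 3.0)
        rev = mm_mechanism("F", 1.5, 0.5, 2.0, substrate="S1", product="S0")
        defaults = dict(E_tot=1.0, F_tot=1.0, S_tot=2.0)
        defaults.update(kw)
        return ModificationCycle(fwd, rev, **defaults)

    def test_ratio_identity(self):
        cycle = self._cycle()
        ae, af = cycle.numeric_aggregated()
        E, F = 0.4, 0.7
        g = substrate_graph(cycle, E, F)
        u = mtt.steady_state_numeric(g)
        expect = (ae.c01 * E + af.c01 * F) / (ae.c10 * E + af.c10 * F)
        assert u[1] / u[0] == pytest.approx(expect, rel=1e-12)

    def test_no_demodification_all_substrate_modified(self):
        """If neither enzyme converts the modified form back (c10 = 0 for
        both), the unmodified form is fully depleted at steady state."""
        cycle = ModificationCycle(
            mm_mechanism("E", 2.0, 1.0, 3.0),
            reversible_mm_mechanism("F", 1.0, 1.0, 1.0, 1.0, kback=0.0,
                                    prefix="f"),   # second kinase-like leg
            E_tot=1.0, F_tot=1.0, S_tot=2.0)
        ae, af = cycle.numeric_aggregated()
        assert ae.c10 == 0 and af.c10 == 0
        st = solve_cycle(cycle)[0]
        assert st.S0 == pytest.approx(0.0, abs=1e-12)
        assert st.S1 > 0

    def test_zero_enzyme_all_unmodified(self):
        from linfra.ptm import _closure
        cycle = self._cycle()
        g = substrate_graph(cycle, 0.0, 0.8)
        assert set(g.edges) == {("S1", "S0")}   # only demodification remains
        ae, af = cycle.numeric_aggregated()
        S0, S1 = _closure(ae, af, cycle.S_tot)(0.0, 0.8)
        assert S1 == pytest.approx(0.0, abs=1e-15)
        assert S0 > 0


class TestReducedSystem:
    def test_no_substrate_identity(self):
        fwd = mm_mechanism("E", 2.0, 1.0, 3.0)
        rev = mm_mechanism("F", 1.5, 0.5, 2.0, substrate="S1", product="S0")
        cycle = ModificationCycle(fwd, rev, E_tot=1.0, F_tot=1.0, S_tot=0.0)
        R_E, R_F, E, F = reduced_system(cycle)
        assert sp.simplify(R_E - E) == 0
        assert sp.simplify(R_F - F) == 0

    def test_sequestration_bound(self):
        fwd = mm_mechanism("E", 2.0, 1.0, 3.0)
        rev = mm_mechanism("F", 1.5, 0.5, 2.0, substrate="S1", product="S0")
        cycle = ModificationCycle(fwd, rev, E_tot=1.0, F_tot=1.0, S_tot=2.0)
        R_E, R_F, E, F = reduced_system(cycle)
        for ev, fv in [(0.1, 0.1), (0.5, 0.9), (1.0, 1.0)]:
            val = float(R_E.subs({E: ev, F: fv}))
            assert val >= ev - 1e-12

    def test_symmetric_cycle_symmetric_root(self):
        fwd = mm_mechanism("E", 2.0, 1.0, 3.0)
        rev = mm_mechanism("F", 2.0, 1.0, 3.0, substrate="S1", product="S0")
        cycle = ModificationCycle(fwd, rev, E_tot=0.5, F_tot=0.5, S_tot=2.0)
        states = solve_cycle(cycle)
        assert len(states) == 1
        st = states[0]
        assert st.E_free == pytest.approx(st.F_free, rel=1e-9)
        assert st.S0 == pytest.approx(st.S1, rel=1e-9)


class TestSolveAndOracle:
    def test_conservation_laws_hold(self):
        cycle = random_cycle(seed=17)
        for st in solve_cycle(cycle):
            e_int = sum(v for y, v in st.intermediates.items()
                        if y in cycle.forward.intermediates)
            f_int = sum(v for y, v in st.intermediates.items()
                        if y in cycle.reverse.intermediates)
            s_int = sum(st.intermediates.values())
            assert st.E_free + e_int == pytest.approx(cycle.E_tot, rel=1e-9)
            assert st.F_free + f_int == pytest.approx(cycle.F_tot, rel=1e-9)
            assert st.S0 + st.S1 + s_int == pytest.approx(cycle.S_tot, rel=1e-9)

    def test_roots_are_ode_steady_states(self):
        """Back-substituted roots are genuine fixed points of the full
        mass-action network."""
        from linfra.ptm import _assemble_network
        for seed in (3, 4, 5):
            cycle = random_cycle(seed=seed)
            species, idx, rhs = _assemble_network(cycle)
            scale = max(cycle.E_tot, cycle.F_tot, cycle.S_tot)
            for st in solve_cycle(cycle):
                u = np.zeros(len(species))
                d = st.as_dict()
                d[cycle.forward.enzyme] = st.E_free
                d[cycle.reverse.enzyme] = st.F_free
                for k, v in d.items():
                    if k in idx:
                        u[idx[k]] = v
                assert np.max(np.abs(rhs(0.0, u))) < 1e-8 * scale

    def test_oracle_conserves_totals(self):
        cycle = random_cycle(seed=23)
        st = ode_oracle(cycle)
        e_int = sum(v for y, v in st.intermediates.items()
                    if y in cycle.forward.intermediates)
        assert st.E_free + e_int == pytest.approx(cycle.E_tot, rel=1e-8)

    def test_oracle_matches_reduced_root(self):
        for seed in (41, 42, 43, 44):
            cycle = random_cycle(seed=seed)
            ref = ode_oracle(cycle)
            states = solve_cycle(cycle)
            best = min(abs(st.E_free - ref.E_free) / max(ref.E_free, 1e-12)
                       + abs(st.F_free - ref.F_free) / max(ref.F_free, 1e-12)
                       for st in states)
            assert best < 1e-6

    def test_goldbeter_koshland_ultrasensitivity(self):
        """Zero-order regime: with both enzymes strongly irreversible and
        substrate far above the Michaelis scale, the modified fraction
        switches sharply as E_tot/F_tot crosses the flux-balance point, and
        sharpens as S_tot grows."""
        def modified_fraction(e_tot, s_tot):
            cycle = ModificationCycle(
                mm_mechanism("E", 10.0, 1.0, 1.0),
                mm_mechanism("F", 10.0, 1.0, 1.0, substrate="S1", product="S0"),
                E_tot=e_tot, F_tot=1.0, S_tot=s_tot)
            st = solve_cycle(cycle)[0]
            return st.S1 / (st.S0 + st.S1)

        ratios = np.array([0.5, 0.9, 1.1, 2.0])
        lo_s = [modified_fraction(r, 5.0) for r in ratios]
        hi_s = [modified_fraction(r, 200.0) for r in ratios]
        # sigmoidal around the balance point E_tot*c01E = F_tot*c10F
        assert hi_s[0] < 0.2 and hi_s[-1] > 0.8
        # steeper transition at larger substrate load
        assert (hi_s[2] - hi_s[1]) > (lo_s[2] - lo_s[1])

    def test_multistationarity_roots_contain_ode_attractors(self):
        """When the reduced system has several positive roots, the state
        reached by integration from different initial conditions is always
        in the root list."""
        # bistable-prone regime: strongly irreversible enzymes, high load
        cycle = ModificationCycle(
            random_order_bibi_mechanism("E", weakly_irreversible=True),
            deadend_phosphatase_mechanism("F", weakly_irreversible=True),
            E_tot=0.5, F_tot=0.5, S_tot=20.0)
        states = solve_cycle(cycle)
        ref = ode_oracle(cycle)
        dists = [abs(st.E_free - ref.E_free) / max(ref.E_free, 1e-12)
                 for st in states]
        assert min(dists) < 1e-5
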