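"""FVA, blocked reactions, dead-end metabolites, span histograms."""

import random

import pytest

from oenoflux.fba import solve_fba
from oenoflux.model import (
    Compartment,
    MetabolicModel,
    Metabolite,
    Reaction,
    ReactionKind,
    build_stoichiometric_matrix,
)
from oenoflux.variability import (
    FluxRange,
    blocked_report,
    find_blocked,
    find_dead_ends_functional,
    find_dead_ends_structural,
    fva,
    span_histogram,
    structural_dead_ends,
)

from conftest import build_chain_model


class TestFVA:
    def test_fixed_uptake_leaves_no_freedom(self):
        model = build_chain_model(uptake_lb=-10, uptake_ub=-10)
        for fr in fva(model):
            assert abs(fr.min_flux) == pytest.approx(10.0)
            assert fr.span == pytest.approx(0.0, abs=1e-8)

    def test_free_uptake_gives_full_ranges(self, chain_model):
        for fr in fva(chain_model):
            lo, hi = sorted((abs(fr.min_flux), abs(fr.max_flux)))
            assert lo == pytest.approx(0.0, abs=1e-9)
            assert hi == pytest.approx(10.0)

    def test_order_independence(self, toy):
        """Ranges are identical under a shuffled reaction order."""
        model, _ = toy
        rids = [r.id for r in model.reactions]
        shuffled = rids[:]
        random.Random(42).shuffle(shuffled)
        a = {fr.reaction_id: (fr.min_flux, fr.max_flux) for fr in fva(model, reactions=rids)}
        b = {fr.reaction_id: (fr.min_flux, fr.max_flux) for fr in fva(model, reactions=shuffled)}
        for rid in rids:
            assert a[rid] == pytest.approx(b[rid], abs=1e-7)

    def test_ranges_contain_fba_optimum(self, toy):
        """At fraction_of_optimum 1 every optimal flux lies inside its range."""
        model, _ = toy
        sol = solve_fba(model)
        ranges = {fr.reaction_id: fr for fr in fva(model, fraction_of_optimum=1.0)}
        for rid, v in sol.fluxes.items():
            fr = ranges[rid]
            assert fr.min_flux - 1e-6 <= v <= fr.max_flux + 1e-6, rid

    def test_cobra_fva_cross_check(self, toy, tmp_path):
        import cobra
        from cobra.flux_analysis import flux_variability_analysis

        from oenoflux.io import write_model_sbml

        model, _ = toy
        write_model_sbml(model, tmp_path / "t.xml")
        cm = cobra.io.read_sbml_model(str(tmp_path / "t.xml"))
        ref = flux_variability_analysis(cm, fraction_of_optimum=0.9, processes=1)
        ours = {fr.reaction_id: fr for fr in fva(model, fraction_of_optimum=0.9)}
        for rid in ref.index:
            assert ours[rid].min_flux == pytest.approx(ref.loc[rid, "minimum"], abs=1e-4)
            assert ours[rid].max_flux == pytest.approx(ref.loc[rid, "maximum"], abs=1e-4)

    def test_infeasible_base_problem_raises_before_solving(self, toy):
        from oenoflux.fba import fix_flux

        model, _ = toy
        broken = fix_flux(model, "BIOMASS", (50.0, 50.0))
        with pytest.raises(RuntimeError, match="infeasible"):
            fva(broken)

    def test_bad_fraction_rejected(self, toy):
        model, _ = toy
        with pytest.raises(ValueError):
            fva(model, fraction_of_optimum=1.5)


class TestBlocked:
    def test_dangling_product_is_blocked(self):
        m = build_chain_model()
        m.add_metabolite(Metabolite("X_c"))
        m.add_reaction(Reaction("RX", stoichiometry={"B_c": -1, "X_c": 1},
                                lower_bound=0, upper_bound=1000))
        assert find_blocked(m) == {"RX"}

    def test_chain_carries_flux_everywhere(self, chain_model):
        assert find_blocked(chain_model) == set()

    def test_invariant_to_order_and_scaling(self, toy_with_orphans):
        model, _, _ = toy_with_orphans
        base = find_blocked(model)
        reordered = model.copy()
        reordered.reactions = list(reversed(reordered.reactions))
        assert find_blocked(reordered) == base
        scaled = model.copy()
        for r in scaled.reactions:
            r.lower_bound *= 2.5
            r.upper_bound *= 2.5
        assert find_blocked(scaled) == base

    def test_blocked_report_subset_relation(self, toy_with_orphans):
        model, truth, _ = toy_with_orphans
        rep = blocked_report(model)
        assert rep.blocked_with_dead_end <= rep.blocked
        assert {f"ORPHSYN{i}" for i in (1, 2, 3)} <= rep.blocked_with_dead_end


class TestStructuralDeadEnds:
    def _mini(self, reactions):
        m = MetabolicModel()
        mets = {mid for stoich, *_ in reactions for mid in stoich}
        for mid in sorted(mets):
            m.add_metabolite(Metabolite(mid))
        for i, (stoich, lb, ub) in enumerate(reactions):
            m.add_reaction(Reaction(f"R{i}", stoichiometry=stoich,
                                    lower_bound=lb, upper_bound=ub))
        return m

    def test_product_with_no_consumer(self):
        m = self._mini([({"A": 1}, 0, 10)])
        S = build_stoichiometric_matrix(m)
        dead = find_dead_ends_structural(S, {"R0": False})
        assert dead == {"A"}

    def test_reversibility_expansion_rescues(self):
        # A <-> B plus B -> C: both A and B gain producer and consumer
        # roles once R0 is expanded into its two directions
        m = self._mini([({"A": -1, "B": 1}, -10, 10), ({"B": -1, "C": 1}, 0, 10)])
        S = build_stoichiometric_matrix(m)
        dead = find_dead_ends_structural(S, {"R0": True, "R1": False})
        assert "B" not in dead
        assert dead == {"C"}  # C is only ever produced

    def test_toy_orphans_are_exactly_recovered(self, toy_with_orphans):
        model, truth, _ = toy_with_orphans
        assert structural_dead_ends(model) == truth.orphan_metabolites


class TestFunctionalDeadEnds:
    def test_structural_implies_functional(self, toy_with_orphans):
        model, _, _ = toy_with_orphans
        assert structural_dead_ends(model) <= find_dead_ends_functional(model)

    def test_unreachable_cycle_is_functionally_dead_only(self):
        """A metabolite producible only from itself: not a structural
        orphan, yet the network can neither make nor drain it."""
        m = MetabolicModel()
        m.add_metabolite(Metabolite("A_c"))
        m.add_metabolite(Metabolite("B_c"))
        m.add_reaction(Reaction("R1", stoichiometry={"A_c": -1, "B_c": 1},
                                lower_bound=0, upper_bound=10))
        m.add_reaction(Reaction("R2", stoichiometry={"B_c": -1, "A_c": 1},
                                lower_bound=0, upper_bound=10))
        S = build_stoichiometric_matrix(m)
        structural = find_dead_ends_structural(S, {"R1": False, "R2": False})
        assert structural == set()  # producer and consumer roles both present structurally
        assert find_dead_ends_functional(m) == {"A_c", "B_c"}

    def test_open_chain_has_no_dead_ends(self, chain_model):
        assert find_dead_ends_functional(chain_model) == set()

    def test_reactions_touching_dead_metabolites_are_blocked(self, toy_with_orphans):
        model, _, _ = toy_with_orphans
        dead = find_dead_ends_functional(model)
        blocked = find_blocked(model)
        for r in model.reactions:
            if any(mid in dead for mid in r.stoichiometry):
                assert r.id in blocked, r.id


class TestSpanHistogram:
    def test_single_bin(self):
        ranges = [FluxRange("a", 0, 10), FluxRange("b", -5, 5)]
        hist, n_zero = span_histogram(ranges)
        assert hist == {1: 2} and n_zero == 0

    def test_one_reaction_per_decade(self):
        ranges = [FluxRange("a", 0, 0.1), FluxRange("b", 0, 1), FluxRange("c", 0, 10)]
        hist, _ = span_histogram(ranges)
        assert hist == {-1: 1, 0: 1, 1: 1}

    def test_zero_span_counted_separately(self):
        ranges = [FluxRange("a", 2, 2), FluxRange("b", 0, 1)]
        hist, n_zero = span_histogram(ranges)
        assert n_zero == 1 and hist == {0: 1}

    def test_constraints_shift_spans_down(self, toy):
        """Experimentally constrained networks have narrower ranges."""
        from oenoflux.fba import fix_flux

        model, _ = toy
        open_ranges = fva(model)
        constrained = model
        for rid, v in (("EX_glc", -1.0), ("EX_fru", -1.0)):
            constrained = fix_flux(constrained, rid, v)
        constrained_ranges = fva(constrained)
        assert sum(fr.span for fr in constrained_ranges) < sum(fr.span for fr in open_ranges)


def test_compartment_enum_is_binary():
    assert {c.value for c in Compartment} == {"intracellular", "extracellular"}
    assert ReactionKind("exchange") is ReactionKind.EXCHANGE
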