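"""Media, omission/carbon screens, deletions, confusion-matrix metrics."""

import math

import numpy as np
import pytest

from oenoflux.fba import solve_fba
from oenoflux.screens import (
    ConfusionMatrix,
    DeletionConfig,
    GrowthCall,
    Medium,
    MediumComponent,
    apply_medium,
    carbon_source_screen,
    classify_outcomes,
    compute_metrics,
    read_medium_tsv,
    single_gene_deletion,
    single_omission_screen,
    single_reaction_deletion,
    write_medium_tsv,
)
from oenoflux.synthetic import validation_calls


class TestApplyMedium:
    def test_empty_medium_starves(self, toy):
        model, _ = toy
        sol = solve_fba(apply_medium(model, Medium([])))
        assert sol.mu == pytest.approx(0.0, abs=1e-9)

    def test_complete_medium_grows(self, toy, toy_medium):
        model, truth = toy
        sol = solve_fba(apply_medium(model, toy_medium))
        assert sol.mu == pytest.approx(truth.optimal_mu, rel=1e-8)

    def test_non_exchange_reaction_rejected(self, toy, toy_medium):
        model, _ = toy
        bad = toy_medium.plus(MediumComponent("weird", "PYK", 1.0))
        with pytest.raises(KeyError, match="PYK"):
            apply_medium(model, bad)

    def test_secretion_bounds_untouched(self, toy, toy_medium):
        model, _ = toy
        constrained = apply_medium(model, toy_medium)
        for r in model.exchanges:
            assert constrained.reaction(r.id).upper_bound == r.upper_bound

    def test_medium_tsv_round_trip(self, toy_medium, tmp_path):
        write_medium_tsv(toy_medium, tmp_path / "m.tsv")
        back = read_medium_tsv(tmp_path / "m.tsv")
        assert [(c.nutrient, c.exchange_id, c.max_uptake, c.always_open)
                for c in back.components] == [
            (c.nutrient, c.exchange_id, c.max_uptake, c.always_open)
            for c in toy_medium.components
        ]


class TestOmissionScreen:
    def test_planted_essential_nutrients_are_called(self, toy, toy_medium):
        """Amino acids with no biosynthesis route, and the cofactor
        precursors, must be essential; everything else must not."""
        model, truth = toy
        calls = single_omission_screen(model, toy_medium)
        essential = {c.item for c in calls if c.essential}
        assert essential == truth.essential_nutrients

    def test_redundant_biosynthesis_makes_nutrient_dispensable(self, toy, toy_medium):
        """Synthesizable amino acids have a transamination shunt."""
        model, _ = toy
        calls = {c.item: c for c in single_omission_screen(model, toy_medium)}
        assert calls["amino_acid_S1"].call == "growth"

    def test_unused_nutrient_is_non_essential(self, toy, toy_medium):
        """A nutrient whose exchange cannot carry uptake flux at any
        optimum (ethanol: its transporter only exports) is dispensable."""
        model, _ = toy
        med = toy_medium.plus(MediumComponent("ethanol", "EX_etoh", 1.0))
        calls = {c.item: c for c in single_omission_screen(model, med)}
        assert calls["ethanol"].call == "growth"

    def test_screen_consistency_by_resolve(self, toy, toy_medium):
        """Re-solving confirms each call against the 20% threshold."""
        model, _ = toy
        calls = single_omission_screen(model, toy_medium)
        for c in calls:
            sol = solve_fba(apply_medium(model, toy_medium.without(c.item)))
            mu = sol.mu if sol.optimal else 0.0
            assert (mu < 0.20 * c.wild_type_mu) == c.essential

    def test_starving_wild_type_rejected(self, toy):
        model, _ = toy
        with pytest.raises(RuntimeError, match="wild type"):
            single_omission_screen(model, Medium([]))


class TestCarbonSourceScreen:
    @pytest.fixture()
    def base_medium(self, toy_medium):
        """The complete medium minus every substrate that can fuel
        biomass on its own: sugars, organic acids, and the synthesizable
        amino acids (without pyruvate from a carbon source the
        transamination shunt is silent, so this base cannot grow)."""
        return Medium([
            c for c in toy_medium.components
            if c.nutrient not in ("glucose", "fructose", "L-malate", "citrate")
            and not c.nutrient.startswith("amino_acid_S")
        ])

    def test_glucose_sustains_growth_alone(self, toy, base_medium):
        model, _ = toy
        calls = carbon_source_screen(
            model, base_medium, [MediumComponent("glucose", "EX_glc", 1.0)]
        )
        assert calls[0].call == "growth"

    def test_unconnected_substrate_cannot(self, toy, base_medium):
        """Acetoin has no uptake route, like a substrate lacking catabolism."""
        model, _ = toy
        calls = carbon_source_screen(
            model, base_medium, [MediumComponent("acetoin", "EX_actn", 1.0)]
        )
        assert calls[0].call == "no_growth"

    def test_empty_source_list(self, toy, base_medium):
        model, _ = toy
        assert carbon_source_screen(model, base_medium, []) == []

    def test_growing_base_medium_rejected(self, toy, toy_medium):
        model, _ = toy
        with pytest.raises(RuntimeError, match="confounded"):
            carbon_source_screen(model, toy_medium, [])


class TestClassifyAndMetrics:
    def test_packaged_validation_table_tally(self):
        calls, in_vivo = validation_calls()
        cm, table = classify_outcomes(calls, in_vivo)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (31, 27, 1, 3)
        assert cm.total == len(table) == 62

    def test_identical_and_inverted_lists(self):
        calls = [GrowthCall(f"n{i}", 1, 1, "growth") for i in range(4)]
        cm, _ = classify_outcomes(calls, {f"n{i}": "growth" for i in range(4)})
        assert (cm.fp, cm.fn) == (0, 0)
        cm, _ = classify_outcomes(calls, {f"n{i}": "no_growth" for i in range(4)})
        assert (cm.tp, cm.tn) == (0, 0) and cm.fp == 4

    def test_missing_label_names_items(self):
        calls = [GrowthCall("x", 1, 1, "growth")]
        with pytest.raises(KeyError, match="x"):
            classify_outcomes(calls, {})

    def test_validation_metrics_match_published_percentages(self):
        metrics = compute_metrics(ConfusionMatrix(tp=31, tn=27, fp=1, fn=3))
        assert metrics.sensitivity == pytest.approx(0.912, abs=5e-4)
        assert metrics.specificity == pytest.approx(0.964, abs=5e-4)
        assert metrics.precision == pytest.approx(0.969, abs=5e-4)
        assert metrics.npv == pytest.approx(0.900, abs=5e-4)
        assert metrics.accuracy == pytest.approx(0.935, abs=5e-4)
        assert metrics.f_score == pytest.approx(0.94, abs=1e-3)  # prints as 94%

    def test_perfect_classifier(self):
        metrics = compute_metrics(ConfusionMatrix(tp=10, tn=10))
        assert all(v == 1.0 for v in metrics.as_dict().values())

    def test_f_score_harmonic_identity(self):
        """precision == sensitivity == p implies F = p."""
        metrics = compute_metrics(ConfusionMatrix(tp=6, tn=0, fp=2, fn=2))
        assert metrics.precision == metrics.sensitivity == pytest.approx(0.75)
        assert metrics.f_score == pytest.approx(0.75)

    def test_undefined_metrics_are_nan_not_zero(self):
        metrics = compute_metrics(ConfusionMatrix(tp=0, tn=5, fp=0, fn=0))
        assert math.isnan(metrics.sensitivity)
        assert math.isnan(metrics.precision)
        assert metrics.specificity == 1.0


class TestDeletions:
    def test_gene_absent_from_gprs_is_dispensable(self, toy, toy_medium):
        model, _ = toy
        m = model.copy()
        from oenoflux.model import Gene

        m.genes.append(Gene("unusedGene"))
        calls = {c.item: c for c in single_gene_deletion(m, toy_medium)}
        assert calls["unusedGene"].call == "growth"

    def test_sole_gene_of_essential_transport_is_essential(self, toy, toy_medium):
        model, _ = toy
        calls = {c.item: c for c in single_gene_deletion(model, toy_medium)}
        assert calls["eaaT1"].essential  # sole carrier of an essential amino acid

    def test_isozyme_pair_is_dispensable(self, toy, toy_medium):
        model, _ = toy
        calls = {c.item: c for c in single_gene_deletion(model, toy_medium)}
        assert not calls["ldhD1"].essential  # "ldhD1 or ldhD2"

    def test_reaction_deletion_ground_truth(self, toy, toy_medium):
        """Exact agreement with the generator's exhaustive re-solve."""
        model, truth = toy
        calls, tally = single_reaction_deletion(model, toy_medium)
        essential = {c.item for c in calls if c.essential}
        assert essential == truth.essential_reactions
        assert sum(tally.values()) == len(essential)

    def test_deleting_biomass_is_essential(self, toy, toy_medium):
        model, _ = toy
        calls = {c.item: c for c in single_reaction_deletion(model, toy_medium)[0]}
        assert calls["BIOMASS"].essential

    def test_deleting_blocked_reaction_changes_nothing(self, toy_with_orphans):
        from oenoflux.synthetic import default_medium

        model, truth, cfg = toy_with_orphans
        med = default_medium(cfg)
        calls = {c.item: c for c in single_reaction_deletion(model, med)[0]}
        c = calls["ORPHSYN1"]
        assert not c.essential
        assert c.perturbed_mu == pytest.approx(c.wild_type_mu, rel=1e-8)

    def test_cobra_deletion_cross_check(self, toy, toy_medium, tmp_path):
        """Essential reactions agree with cobrapy's deletion screen."""
        import cobra
        from cobra.flux_analysis import single_reaction_deletion as cobra_del

        from oenoflux.io import write_model_sbml

        model, truth = toy
        write_model_sbml(model, tmp_path / "t.xml")
        cm = cobra.io.read_sbml_model(str(tmp_path / "t.xml"))
        wt = cm.slim_optimize()
        frame = cobra_del(cm, processes=1)
        essential = set()
        for ids, growth in zip(frame["ids"], frame["growth"]):
            mu = 0.0 if (growth is None or np.isnan(growth)) else growth
            if mu < 0.2 * wt:
                essential |= set(ids)
        assert essential == truth.essential_reactions


def test_medium_monotonicity_seeded(toy, toy_medium):
    """Adding a nutrient back never lowers the optimum (spot check; the
    full 100-pair sweep lives in the acceptance suite)."""
    model, _ = toy
    rng = np.random.default_rng(7)
    full_mu = solve_fba(apply_medium(model, toy_medium)).mu
    names = [c.nutrient for c in toy_medium.screenable]
    for _ in range(10):
        dropped = rng.choice(names)
        sub = toy_medium.without(dropped)
        mu_sub = solve_fba(apply_medium(model, sub)).mu
        assert mu_sub <= full_mu + 1e-8


def test_deletion_config_validation():
    with pytest.raises(ValueError):
        DeletionConfig(essentiality_reduction_threshold=1.5)
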