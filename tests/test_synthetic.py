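"""The toy heterofermentative LAB generator and packaged validation data."""

import numpy as np
import pytest

from oenoflux.fba import solve_fba
from oenoflux.model import ReactionKind
from oenoflux.screens import Medium, MediumComponent, apply_medium
from oenoflux.synthetic import (
    ToyNetworkConfig,
    carbon_count,
    default_medium,
    load_validation_table,
    make_reduced_toy_model,
    make_synthetic_rates,
    make_toy_lab_model,
    random_toy_config,
    validation_calls,
)


class TestGenerator:
    def test_default_network_grows_on_complete_medium(self, toy, toy_medium):
        model, truth = toy
        sol = solve_fba(apply_medium(model, toy_medium))
        assert sol.mu > 1e-6
        assert sol.mu == pytest.approx(truth.optimal_mu, rel=1e-8)

    def test_no_growth_on_empty_medium(self, toy):
        model, _ = toy
        assert solve_fba(apply_medium(model, Medium([]))).mu == pytest.approx(0.0, abs=1e-9)

    def test_malate_feeds_the_proton_gradient(self, toy, toy_medium):
        """Malolactic decarboxylation consumes a cytosolic proton and
        exports lactate+H+; the synthase converts the gradient to ATP,
        so malate strictly raises growth."""
        model, _ = toy
        mu_with = solve_fba(apply_medium(model, toy_medium)).mu
        mu_without = solve_fba(apply_medium(model, toy_medium.without("L-malate"))).mu
        assert mu_with > mu_without + 1e-6

    def test_redox_valves_matter_on_fructose(self):
        """Without mannitol/erythritol branches and without oxygen,
        fructose-only growth is strictly lower (NAD+ regeneration must
        fall back on the ATP-costly ethanol branch)."""

        def fructose_only_mu(cfg):
            model, _ = make_toy_lab_model(cfg, compute_essentials=False)
            comps = [
                MediumComponent("fructose", "EX_fru", 1.0),
                MediumComponent("water", "EX_h2o", 1000.0, always_open=True),
                MediumComponent("phosphate", "EX_pi", 1000.0, always_open=True),
                MediumComponent("nicotinate", "EX_nab", 1.0),
                MediumComponent("adenine", "EX_adeb", 1.0),
            ]
            for i in range(1, cfg.n_essential_amino_acids + 1):
                comps.append(MediumComponent(f"aaE{i}", f"EX_aaE{i}", 0.5))
            for i in range(1, cfg.n_synthesizable_amino_acids + 1):
                comps.append(MediumComponent(f"aaS{i}", f"EX_aaS{i}", 2.0))
            sol = solve_fba(apply_medium(model, Medium(comps)))
            return sol.mu if sol.optimal else 0.0

        with_valves = fructose_only_mu(ToyNetworkConfig())
        without = fructose_only_mu(
            ToyNetworkConfig(mannitol_branch=False, erythritol_branch=False)
        )
        assert without < with_valves - 1e-6

    def test_orphan_metabolites_are_planted_exactly(self, toy_with_orphans):
        from oenoflux.variability import structural_dead_ends

        model, truth, cfg = toy_with_orphans
        assert len(truth.orphan_metabolites) == cfg.planted_orphan_metabolites
        assert structural_dead_ends(model) == truth.orphan_metabolites

    def test_carbon_balance_of_internal_reactions(self, toy_with_orphans):
        model, _, _ = toy_with_orphans
        for r in model.reactions:
            if r.kind in (ReactionKind.EXCHANGE, ReactionKind.BIOMASS):
                continue
            balance = sum(c * carbon_count(m) for m, c in r.stoichiometry.items())
            assert abs(balance) < 1e-9, r.id

    def test_ground_truth_essentials_confirmed_by_screen(self, toy, toy_medium):
        from oenoflux.screens import single_reaction_deletion

        model, truth = toy
        calls, _ = single_reaction_deletion(model, toy_medium)
        assert {c.item for c in calls if c.essential} == truth.essential_reactions

    @pytest.mark.parametrize("seed", range(8))
    def test_random_variants_are_valid_and_grow(self, seed):
        cfg = random_toy_config(seed)
        model, truth = make_toy_lab_model(cfg, compute_essentials=False)
        model.validate()
        assert truth.optimal_mu > 1e-6
        assert solve_fba(apply_medium(model, Medium([]))).mu == pytest.approx(0, abs=1e-9)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ToyNetworkConfig(n_essential_amino_acids=-1)
        with pytest.raises(ValueError):
            ToyNetworkConfig(protons_per_atp=0)

    def test_reduced_model_is_small_and_solvable(self):
        model = make_reduced_toy_model()
        assert len(model.reactions) <= 10
        assert solve_fba(model).mu > 0


class TestSyntheticRates:
    def test_same_seed_reproduces_rates(self, toy):
        model, _ = toy
        a, _ = make_synthetic_rates(model, 2.0, 0.02, seed=5)
        b, _ = make_synthetic_rates(model, 2.0, 0.02, seed=5)
        assert [(r.reaction_id, r.rate) for r in a.records] == [
            (r.reaction_id, r.rate) for r in b.records
        ]

    def test_different_seed_changes_noise(self, toy):
        model, _ = toy
        a, _ = make_synthetic_rates(model, 2.0, 0.02, seed=5)
        b, _ = make_synthetic_rates(model, 2.0, 0.02, seed=6)
        assert [r.rate for r in a.records] != [r.rate for r in b.records]

    def test_directions_match_flux_signs(self, toy):
        model, _ = toy
        rates, _ = make_synthetic_rates(model, 1.0, 0.0, seed=0)
        directions = {r.reaction_id: r.direction for r in rates.records}
        assert directions["EX_glc"] == "consumption"
        assert directions["EX_dlac"] == "production"

    def test_out_of_range_ngam_rejected(self, toy):
        model, _ = toy
        with pytest.raises(ValueError):
            make_synthetic_rates(model, 7.0, 0.0, seed=0)

    def test_truth_records_generating_value(self, toy):
        model, _ = toy
        rates, truth = make_synthetic_rates(model, 1.3, 0.0, seed=0)
        assert truth.true_ngam == 1.3
        assert rates.observed_mu == pytest.approx(truth.optimal_mu)


class TestValidationTable:
    def test_shape_and_categories(self):
        df = load_validation_table()
        assert len(df) == 62
        assert df.category.value_counts().to_dict() == {
            "amino_acid": 20, "carbon_source": 18, "vitamin": 11,
            "mineral": 7, "nucleotide": 6,
        }

    @pytest.mark.parametrize(
        "item,label",
        [("Esculin", "FN"), ("Salicin", "FN"), ("L-Glutamic acid", "FP"),
         ("L-Serine", "FN"), ("D-Glucose", "TP"), ("Glycerol", "TN")],
    )
    def test_printed_labels(self, item, label):
        df = load_validation_table().set_index("item")
        assert df.loc[item, "result"] == label

    def test_stored_labels_are_consistent_with_calls(self):
        """The printed TP/TN/FP/FN column agrees with the +/- columns."""
        df = load_validation_table()
        for row in df.itertuples():
            expected = {("+", "+"): "TP", ("-", "-"): "TN",
                        ("-", "+"): "FP", ("+", "-"): "FN"}[(row.in_vivo, row.in_silico)]
            assert row.result == expected

    def test_calls_view_total(self):
        calls, in_vivo = validation_calls()
        assert len(calls) == len(in_vivo) == 62
        assert np.mean([c.call == "growth" for c in calls]) > 0
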