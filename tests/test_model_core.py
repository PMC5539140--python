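"""Model validation, TAG augmentation, knockouts and gene mapping."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tagknock import (
    Metabolite,
    ModelError,
    Reaction,
    StoichiometricModel,
    apply_knockouts,
    augment_tag_synthesis,
    genes_for_candidate,
    revert_delta,
    solve_fba,
    validate_model,
)
from tagknock.io import model_to_dict


def _three_step_chain():
    return StoichiometricModel(
        id="chain3",
        metabolites=[Metabolite("A", compartment="e"), Metabolite("B")],
        reactions=[
            Reaction("EX_A", stoichiometry={"A": -1.0}, lower_bound=-10.0),
            Reaction("T_A", stoichiometry={"A": -1.0, "B": 1.0}),
            Reaction("BIO", stoichiometry={"B": -1.0}, objective_coefficient=1.0),
        ],
        objective_reaction_id="BIO",
    )


class TestValidation:
    def test_well_formed_model_has_empty_report(self):
        report = validate_model(_three_step_chain())
        assert report.ok and report.issues == []

    def test_unknown_metabolite_reference_is_flagged(self):
        model = _three_step_chain()
        model.reactions[1].stoichiometry["x_missing"] = 1.0
        report = validate_model(model)
        errors = report.errors()
        assert len(errors) == 1
        assert errors[0].target_id == "T_A"
        assert "x_missing" in errors[0].message

    def test_inverted_bounds_are_flagged(self):
        model = _three_step_chain()
        model.reactions[2].lower_bound = 5.0
        model.reactions[2].upper_bound = 1.0
        report = validate_model(model)
        assert len(report.errors()) == 1
        assert report.errors()[0].target_id == "BIO"

    def test_duplicate_ids_and_missing_objective(self):
        model = _three_step_chain()
        model.reactions.append(model.reactions[0].copy())
        model.objective_reaction_id = "NOPE"
        report = validate_model(model)
        messages = " ".join(i.message for i in report.errors())
        assert "duplicate reaction" in messages and "NOPE" in messages

    def test_validation_never_mutates(self):
        model = _three_step_chain()
        snapshot = model_to_dict(model)
        validate_model(model)
        assert model_to_dict(model) == snapshot


def _tag_precursor_toy():
    """Minimal model carrying DAG/acyl-CoA/CoA species plus a boundary feed."""
    return StoichiometricModel(
        id="tag_precursors",
        metabolites=[
            Metabolite("dag_c"),
            Metabolite("acylcoa_c"),
            Metabolite("coa_c"),
        ],
        reactions=[
            Reaction("SRC_dag", stoichiometry={"dag_c": 1.0}, upper_bound=10.0),
            Reaction("SRC_acyl", stoichiometry={"acylcoa_c": 1.0}, upper_bound=10.0),
            Reaction("DM_coa", stoichiometry={"coa_c": -1.0}),
            Reaction("BIO", stoichiometry={"dag_c": -0.1}, objective_coefficient=1.0),
        ],
        objective_reaction_id="BIO",
    )


class TestAugmentation:
    def test_adds_dgat_demand_and_tag_species(self):
        model = _tag_precursor_toy()
        augmented, delta = augment_tag_synthesis(
            model, dag_id="dag_c", acyl_coa_ids=["acylcoa_c"], tag_id="tag_c",
            coa_id="coa_c", add_demand=True,
        )
        assert len(augmented.reactions) == len(model.reactions) + 2
        assert len(augmented.metabolites) == len(model.metabolites) + 1
        dgat = augmented.get_reaction("DGAT_acylcoa_c")
        assert dgat.stoichiometry == {"dag_c": -1.0, "acylcoa_c": -1.0, "tag_c": 1.0, "coa_c": 1.0}
        assert (dgat.lower_bound, dgat.upper_bound) == (0.0, model.default_bound)
        assert {r.id for r in delta.added_reactions} == {"DGAT_acylcoa_c", "DM_tag"}

    def test_without_demand_tag_is_dead_end(self):
        model = _tag_precursor_toy()
        augmented, _ = augment_tag_synthesis(
            model, dag_id="dag_c", acyl_coa_ids=["acylcoa_c"], tag_id="tag_c",
            coa_id="coa_c", add_demand=False,
        )
        assert len(augmented.reactions) == len(model.reactions) + 1
        sol = solve_fba(augmented, objective_reaction_id="DGAT_acylcoa_c")
        assert sol.optimal and abs(sol.objective_value) <= 1e-6

    def test_growth_optimum_unchanged_on_redox_toy(self, redox):
        model, truth = redox
        augmented, _ = augment_tag_synthesis(
            model, dag_id="p", acyl_coa_ids=["nadh"], tag_id="tag", coa_id="eth",
            add_demand=True,
        )
        before = solve_fba(model).objective_value
        after = solve_fba(augmented).objective_value
        assert before == pytest.approx(truth.max_growth, abs=1e-6)
        assert after == pytest.approx(before, abs=1e-6)

    def test_biomass_reaction_is_bit_identical(self, redox):
        model, _ = redox
        augmented, _ = augment_tag_synthesis(
            model, dag_id="p", acyl_coa_ids=["nadh"], tag_id="tag", coa_id="eth",
        )
        assert augmented.objective_reaction.stoichiometry == model.objective_reaction.stoichiometry
        assert augmented.objective_reaction.lower_bound == model.objective_reaction.lower_bound
        assert augmented.objective_reaction.upper_bound == model.objective_reaction.upper_bound

    def test_delta_revert_restores_serialization(self, redox):
        model, _ = redox
        before = model_to_dict(model)
        augmented, delta = augment_tag_synthesis(
            model, dag_id="p", acyl_coa_ids=["nadh"], tag_id="tag", coa_id="eth",
        )
        assert model_to_dict(revert_delta(augmented, delta)) == before

    def test_unknown_species_and_collisions_raise(self, redox):
        model, _ = redox
        with pytest.raises(ModelError, match="ghost"):
            augment_tag_synthesis(model, "ghost", ["nadh"], "tag", "eth")
        augmented, _ = augment_tag_synthesis(model, "p", ["nadh"], "tag", "eth")
        with pytest.raises(ModelError, match="DGAT_nadh"):
            augment_tag_synthesis(augmented, "p", ["nadh"], "tag", "eth")
        with pytest.raises(ModelError, match="distinct"):
            augment_tag_synthesis(model, "p", ["p"], "tag", "eth")


class TestKnockouts:
    def test_empty_knockout_is_identity(self, redox):
        model, _ = redox
        assert apply_knockouts(model, set()) == model

    def test_uptake_knockout_kills_growth(self, chain):
        model, _ = chain
        knocked = apply_knockouts(model, {"T_A"})
        assert solve_fba(knocked).objective_value == pytest.approx(0.0, abs=1e-9)

    def test_fermentation_knockout_drops_growth(self, redox):
        model, _ = redox
        assert solve_fba(model).objective_value == pytest.approx(7.5, abs=1e-6)
        knocked = solve_fba(apply_knockouts(model, {"FERM_E"}))
        assert knocked.objective_value == pytest.approx(5.0, abs=1e-6)

    def test_unknown_reaction_raises(self, redox):
        model, _ = redox
        with pytest.raises(ModelError, match="NOPE"):
            apply_knockouts(model, {"NOPE"})

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.data())
    def test_monotonicity_under_nested_knockouts(self, data):
        """Deleting more reactions can never raise the growth optimum."""
        from tagknock import make_redox_coupled_toy

        model, _ = make_redox_coupled_toy()
        knockable = ["GLY", "RESP", "FERM_E", "FERM_T"]
        b = data.draw(st.sets(st.sampled_from(knockable)))
        a = data.draw(st.sets(st.sampled_from(sorted(b)))) if b else set()
        opt = lambda ko: solve_fba(apply_knockouts(model, ko)).objective_value
        assert opt(b) <= opt(a) + 1e-6


class TestGeneMapping:
    def test_genes_preserve_order(self, redox):
        model, _ = redox
        mapping = genes_for_candidate(model, {"GLY", "DM_tag"})
        assert mapping["GLY"] == ["SCO5426", "SCO2119", "SCO1214"]
        assert mapping["DM_tag"] == []

    def test_table_style_row(self):
        model = _three_step_chain()
        model.reactions[1].id = "ECOAH8"
        model.reactions[1].gene_association = "SCO6732 or SCO4384"
        assert genes_for_candidate(model, {"ECOAH8"}) == {"ECOAH8": ["SCO6732", "SCO4384"]}

    def test_unknown_reaction_raises(self, redox):
        model, _ = redox
        with pytest.raises(ModelError):
            genes_for_candidate(model, {"missing"})
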