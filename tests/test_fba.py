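"""FBA engine: optima, variability, lexicographic scoring, chemostat
prediction, duality, and an independent COBRA/GLPK cross-check."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tagknock import (
    ChemostatCondition,
    apply_knockouts,
    flux_variability,
    make_chemostat_fixture,
    make_linear_chain,
    make_redox_coupled_toy,
    maximize_product_at_growth,
    predict_chemostat_growth,
    solve_fba,
)
from tagknock.fba import InfeasibleProblemError, check_solution


class TestSolveFBA:
    @pytest.mark.parametrize("uptake", [10.0, 0.0, 3.9])
    def test_linear_chain_optimum_equals_uptake(self, uptake):
        model, truth = make_linear_chain(uptake)
        sol = solve_fba(model)
        assert sol.optimal
        assert sol.objective_value == pytest.approx(truth.max_growth, abs=1e-9)

    def test_redox_coupled_optimum_and_unique_fluxes(self, redox):
        model, truth = redox
        sol = solve_fba(model)
        assert sol.objective_value == pytest.approx(7.5, abs=1e-6)
        assert sol.fluxes["FERM_E"] == pytest.approx(5.0, abs=1e-6)
        assert sol.fluxes["FERM_T"] == pytest.approx(0.0, abs=1e-6)

    def test_minimization_direction(self, redox):
        model, _ = redox
        sol = solve_fba(model, direction="min")
        assert sol.objective_value == pytest.approx(0.0, abs=1e-6)

    def test_solution_certificate(self, redox):
        model, _ = redox
        sol = solve_fba(model)
        assert check_solution(model, sol)

    def test_duals_satisfy_strong_duality(self, redox):
        """LP strong duality: the optimum equals the dual bound terms
        (steady-state rows contribute zero since their RHS is zero)."""
        model, _ = redox
        sol = solve_fba(model)
        assert sol.duals is not None
        # dual objective = sum over reactions of bound * reduced-cost terms;
        # reconstruct reduced costs from the metabolite duals: z_j = c_j - S_j·y
        dual_obj = 0.0
        for rxn in model.reactions:
            c_j = 1.0 if rxn.id == model.objective_reaction_id else 0.0
            z = c_j - sum(coeff * sol.duals[met] for met, coeff in rxn.stoichiometry.items())
            if z > 0:
                dual_obj += rxn.upper_bound * z
            else:
                dual_obj += rxn.lower_bound * z
        assert dual_obj == pytest.approx(sol.objective_value, abs=1e-6)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.floats(min_value=0.01, max_value=50.0, allow_nan=False))
    def test_scaling_equivariance(self, k):
        """Scaling all bounds by k > 0 scales the optimum by k."""
        model, _ = make_redox_coupled_toy()
        base = solve_fba(model).objective_value
        scaled = model.copy()
        for rxn in scaled.reactions:
            rxn.lower_bound *= k
            rxn.upper_bound *= k
        assert solve_fba(scaled).objective_value == pytest.approx(k * base, rel=1e-6)

    def test_knockout_consistency_with_manual_bound_zeroing(self, redox):
        model, _ = redox
        via_op = solve_fba(apply_knockouts(model, {"RESP"}))
        manual = model.copy()
        rxn = manual.get_reaction("RESP")
        rxn.lower_bound = rxn.upper_bound = 0.0
        assert via_op.objective_value == pytest.approx(
            solve_fba(manual).objective_value, abs=1e-9
        )

    def test_cross_check_against_cobrapy_glpk(self, redox):
        """Independent oracle: the same model built in COBRApy and solved
        with GLPK must agree with the in-house HiGHS LP."""
        cobra = pytest.importorskip("cobra")
        model, _ = redox
        cm = cobra.Model(model.id)
        cm.add_metabolites([cobra.Metabolite(m.id) for m in model.metabolites])
        for rxn in model.reactions:
            cr = cobra.Reaction(rxn.id)
            cm.add_reactions([cr])
            cr.add_metabolites(
                {cm.metabolites.get_by_id(k): v for k, v in rxn.stoichiometry.items()}
            )
            cr.bounds = (rxn.lower_bound, rxn.upper_bound)
        cm.solver = "glpk"
        cm.objective = cm.reactions.get_by_id(model.objective_reaction_id)
        assert cm.slim_optimize() == pytest.approx(solve_fba(model).objective_value, abs=1e-6)


class TestVariability:
    def test_fully_determined_chain(self, chain):
        model, _ = chain
        ranges = {r.reaction_id: r for r in flux_variability(model, 1.0)}
        assert ranges["EX_A"].min_flux == pytest.approx(-10.0, abs=1e-6)
        assert ranges["EX_A"].max_flux == pytest.approx(-10.0, abs=1e-6)
        assert ranges["T_A"].min_flux == pytest.approx(10.0, abs=1e-6)
        assert ranges["BIO"].max_flux == pytest.approx(10.0, abs=1e-6)

    def test_redox_tag_branch_pinned_at_optimum(self, redox):
        model, _ = redox
        ranges = {r.reaction_id: r for r in flux_variability(model, 1.0)}
        assert ranges["FERM_T"].min_flux == pytest.approx(0.0, abs=1e-6)
        assert ranges["FERM_T"].max_flux == pytest.approx(0.0, abs=1e-6)
        obj = ranges[model.objective_reaction_id]
        assert obj.min_flux == pytest.approx(7.5, abs=1e-6)
        assert obj.max_flux == pytest.approx(7.5, abs=1e-6)

    def test_infeasible_base_raises(self, chain):
        model, _ = chain
        model.get_reaction("BIO").lower_bound = 11.0  # demand above capacity
        with pytest.raises(InfeasibleProblemError):
            flux_variability(model, 1.0)


class TestLexicographicScoring:
    def test_wild_type_optimistic_product_is_zero(self, redox):
        model, _ = redox
        sol = maximize_product_at_growth(model, "DM_tag", 1.0)
        assert sol.growth_optimum == pytest.approx(7.5, abs=1e-6)
        assert sol.objective_value == pytest.approx(0.0, abs=1e-6)

    def test_knockout_redirects_flux_to_product(self, redox):
        model, _ = redox
        knocked = apply_knockouts(model, {"FERM_E"})
        sol = maximize_product_at_growth(knocked, "DM_tag", 1.0)
        assert sol.growth_optimum == pytest.approx(5.0, abs=1e-6)
        assert sol.objective_value == pytest.approx(10.0, abs=1e-6)

    def test_zero_growth_fraction_is_plain_product_maximization(self, redox):
        model, _ = redox
        sol = maximize_product_at_growth(model, "DM_tag", 0.0)
        # with no growth requirement all carbon can go to TAG: z = 2g - 10
        # is not binding anymore; p-balance allows z up to 2g with nadh 2g = z
        assert sol.objective_value > 10.0 - 1e-6


class TestChemostat:
    def test_consistent_measurement_reproduces_dilution_rate(self):
        model, condition, _ = make_chemostat_fixture(0.039, 1.0)
        pred = predict_chemostat_growth(model, condition)
        assert pred.predicted_growth == pytest.approx(0.039, abs=1e-9)
        assert pred.relative_error == pytest.approx(0.0, abs=1e-9)

    def test_mismatched_measurement_yields_relative_error(self):
        model, condition, truth = make_chemostat_fixture(0.039, 1.0, uptake_rate=0.042)
        pred = predict_chemostat_growth(model, condition)
        assert pred.predicted_growth == pytest.approx(0.042, abs=1e-9)
        assert pred.relative_error == pytest.approx(abs(0.042 - 0.039) / 0.039, abs=1e-9)
        assert pred.relative_error == pytest.approx(truth.extra["relative_error"], abs=1e-12)

    def test_zero_uptake_gives_zero_growth(self):
        model, _, _ = make_chemostat_fixture(0.039, 1.0)
        condition = ChemostatCondition(0.039, {"EX_s": (0.0, 0.0)})
        pred = predict_chemostat_growth(model, condition)
        assert pred.predicted_growth == pytest.approx(0.0, abs=1e-9)

    def test_yield_scales_linearly(self):
        model, condition, _ = make_chemostat_fixture(0.039, 0.5, uptake_rate=0.078)
        pred = predict_chemostat_growth(model, condition)
        assert pred.predicted_growth == pytest.approx(0.039, abs=1e-9)

    def test_unknown_exchange_id_raises(self):
        model, _, _ = make_chemostat_fixture(0.039, 1.0)
        condition = ChemostatCondition(0.039, {"EX_ghost": (-1.0, 0.0)})
        with pytest.raises(Exception, match="EX_ghost"):
            predict_chemostat_growth(model, condition)
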