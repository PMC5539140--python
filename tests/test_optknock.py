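"""Knockout design: MILP formulation, enumeration with cuts, the brute-force
oracle, and their equivalence."""

import pytest

from tagknock import (
    KnockoutCandidate,
    OptKnockConfig,
    brute_force_knockouts,
    enumerate_candidates,
    formulate_optknock,
    make_redox_coupled_toy,
    make_tag_toy,
    maximize_product_at_growth,
    select_knockable,
    verify_candidate,
)
from tagknock.optknock import export_lp_text

from conftest import tag_config


def _ranked(cands):
    return [
        (tuple(sorted(c.deleted_reaction_ids)), round(c.outer_objective, 6), round(c.inner_objective, 6))
        for c in cands
    ]


class TestSelectKnockable:
    def test_redox_default_rule(self, redox):
        model, _ = redox
        knockable = select_knockable(model, tag_config())
        assert knockable == {"GLY", "RESP", "FERM_E", "FERM_T"}

    def test_explicit_set_passthrough(self, redox):
        model, _ = redox
        cfg = tag_config()
        cfg.knockable_reaction_ids = {"FERM_E"}
        assert select_knockable(model, cfg) == {"FERM_E"}

    def test_empty_result_raises(self, chain):
        model, _ = chain
        cfg = OptKnockConfig(target_reaction_id="T_A", biomass_reaction_id="BIO")
        with pytest.raises(ValueError):
            select_knockable(model, cfg)  # the only internal reaction is the target


class TestFormulation:
    def test_one_binary_per_knockable(self, redox):
        model, _ = redox
        problem = formulate_optknock(model, tag_config())
        assert int(problem.integrality.sum()) == 4
        assert problem.knockable_ids == ["FERM_E", "FERM_T", "GLY", "RESP"]

    def test_k_zero_collapses_to_wild_type_lexicographic_lp(self, redox):
        model, _ = redox
        cfg = tag_config(K=0)
        cands = enumerate_candidates(model, cfg)
        wt = maximize_product_at_growth(model, "DM_tag", growth_fraction=1.0)
        assert len(cands) == 1 and cands[0].deleted_reaction_ids == frozenset()
        assert cands[0].outer_objective == pytest.approx(wt.objective_value, abs=1e-6)
        assert cands[0].verified

    def test_lp_export_is_textual(self, redox):
        model, _ = redox
        text = export_lp_text(formulate_optknock(model, tag_config()))
        assert "Maximize" in text and "Binaries" in text

    def test_nonfinite_bounds_rejected(self, redox):
        model, _ = redox
        model.get_reaction("GLY").upper_bound = float("inf")
        with pytest.raises(ValueError, match="non-finite"):
            formulate_optknock(model, tag_config())


class TestEnumeration:
    def test_redox_ground_truth_rank_one(self, redox):
        model, truth = redox
        cands = enumerate_candidates(model, tag_config(K=1, n=3))
        assert cands, "expected at least one candidate"
        top = cands[0]
        deleted, outer, inner = truth.best_single_knockout
        assert top.deleted_reaction_ids == deleted
        assert top.outer_objective == pytest.approx(outer, abs=1e-6)
        assert top.inner_objective == pytest.approx(inner, abs=1e-6)
        assert top.verified

    def test_duality_gap_small_at_every_solution(self, redox):
        model, _ = redox
        for cand in enumerate_candidates(model, tag_config(K=2, n=5)):
            assert cand.duality_gap is not None and cand.duality_gap <= 1e-6

    def test_cut_soundness_no_repeats_or_supersets(self):
        model, _ = make_tag_toy(n_extra_branches=6, seed=5)
        cands = enumerate_candidates(model, tag_config(K=2, n=10))
        seen = []
        for cand in cands:
            for prev in seen:
                assert not cand.deleted_reaction_ids >= prev, (
                    f"{sorted(cand.deleted_reaction_ids)} repeats/subsumes {sorted(prev)}"
                )
            seen.append(cand.deleted_reaction_ids)

    def test_rank_one_outer_monotone_in_k(self):
        model, _ = make_tag_toy(n_extra_branches=4, seed=2)
        best = [
            enumerate_candidates(model, tag_config(K=K, n=1))[0].outer_objective
            for K in (1, 2)
        ]
        assert best[1] >= best[0] - 1e-6

    def test_rank_one_at_least_wild_type_optimistic(self):
        model, _ = make_tag_toy(n_extra_branches=4, seed=4)
        wt = maximize_product_at_growth(model, "DM_tag", growth_fraction=1.0)
        top = enumerate_candidates(model, tag_config(K=1, n=1))[0]
        assert top.outer_objective >= wt.objective_value - 1e-6


class TestOracleEquivalence:
    def test_redox_k1_and_k2(self, redox):
        model, _ = redox
        for K in (1, 2):
            cfg = tag_config(K=K, n=10)
            assert _ranked(enumerate_candidates(model, cfg)) == _ranked(
                brute_force_knockouts(model, cfg)
            )

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_seeded_tag_toys(self, seed):
        model, _ = make_tag_toy(n_extra_branches=4, seed=seed)
        for K in (1, 2):
            cfg = tag_config(K=K, n=10)
            milp = _ranked(enumerate_candidates(model, cfg))
            oracle = _ranked(brute_force_knockouts(model, cfg))
            assert milp == oracle, f"seed={seed} K={K}: {milp} != {oracle}"

    def test_k_zero_single_record(self, redox):
        model, _ = redox
        cands = brute_force_knockouts(model, tag_config(K=0))
        wt = maximize_product_at_growth(model, "DM_tag", growth_fraction=1.0)
        assert len(cands) == 1
        assert cands[0].deleted_reaction_ids == frozenset()
        assert cands[0].outer_objective == pytest.approx(wt.objective_value, abs=1e-6)

    def test_brute_force_guard(self):
        big = make_tag_toy(n_extra_branches=10, seed=0)[0]
        huge = OptKnockConfig("DM_tag", "BIO", max_deletions=10, n_candidates=1)
        with pytest.raises(ValueError, match="guard"):
            brute_force_knockouts(big, huge)


class TestVerification:
    def test_falsified_outer_objective_is_flagged(self, redox):
        model, _ = redox
        fake = KnockoutCandidate(frozenset({"FERM_E"}), outer_objective=99.0, inner_objective=5.0)
        checked = verify_candidate(model, tag_config(), fake)
        assert not checked.verified and "mismatch" in checked.diagnostic

    def test_true_candidate_verifies(self, redox):
        model, _ = redox
        cand = KnockoutCandidate(frozenset({"FERM_E"}), outer_objective=10.0, inner_objective=5.0)
        assert verify_candidate(model, tag_config(), cand).verified

    def test_wild_type_record_verifies(self, redox):
        model, _ = redox
        wt = maximize_product_at_growth(model, "DM_tag", growth_fraction=1.0)
        cand = KnockoutCandidate(
            frozenset(), outer_objective=wt.objective_value, inner_objective=wt.growth_optimum
        )
        assert verify_candidate(model, tag_config(), cand).verified
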