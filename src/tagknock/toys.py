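"""Synthetic toy metabolic models with analytically known ground truth.

Genome-scale models are too large for exhaustive verification, so every
engine in this package is exercised on small fixtures that reproduce the
structural features the analysis depends on: a biomass objective, a limited
carbon uptake, a redox (NADH) balance that couples pathways, a TAG branch
fed by acyl-CoA and DAG, competing drain pathways (a fermentative sink, a
β-oxidation-like recycle, byproduct secretions), and gene associations for
GPR bookkeeping.  Each generator returns the model together with a
:class:`ToyGroundTruth` carrying values that the LP engine and the knockout
engines must reproduce.

Fixed fixtures carry hand-derived optima (see the notes fields); the
randomized TAG fixture is *self-certifying* — its ground truth is computed
at generation time by the brute-force oracle so that the MILP engine is
always tested against an independent computation path.

Flux units are nominal mmol·gDCW⁻¹·h⁻¹; only ratios matter for the
properties tested.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .core import Metabolite, Reaction, StoichiometricModel, augment_tag_synthesis
from .fba import ChemostatCondition, maximize_product_at_growth, solve_fba
from .optknock import OptKnockConfig, brute_force_knockouts

__all__ = [
    "ToyGroundTruth",
    "make_linear_chain",
    "make_redox_coupled_toy",
    "make_tag_toy",
    "make_chemostat_fixture",
]


@dataclass
class ToyGroundTruth:
    max_growth: float
    optimistic_product_at_max_growth: float | None = None
    best_single_knockout: tuple[frozenset, float, float] | None = None
    notes: str = ""
    extra: dict = field(default_factory=dict)


def _met(mid: str, name: str = "", compartment: str = "c") -> Metabolite:
    return Metabolite(id=mid, name=name or mid, compartment=compartment)


def make_linear_chain(uptake_limit: float) -> tuple[StoichiometricModel, ToyGroundTruth]:
    """Single-path network: EX_A (uptake) → T_A → BIO.

    Conservation along the only path pins the growth optimum at the uptake
    limit, making this the simplest analytic FBA fixture.
    """
    if uptake_limit < 0:
        raise ValueError(f"uptake_limit must be ≥ 0, got {uptake_limit}")
    model = StoichiometricModel(
        id="linear_chain",
        metabolites=[_met("A", compartment="e"), _met("B")],
        reactions=[
            Reaction("EX_A", "A exchange", {"A": -1.0}, -uptake_limit, 1000.0),
            Reaction("T_A", "A assimilation", {"A": -1.0, "B": 1.0}, 0.0, 1000.0),
            Reaction("BIO", "biomass", {"B": -1.0}, 0.0, 1000.0, objective_coefficient=1.0),
        ],
        objective_reaction_id="BIO",
    )
    truth = ToyGroundTruth(
        max_growth=float(uptake_limit),
        notes="single path; growth equals the uptake bound by conservation",
    )
    return model, truth


def make_redox_coupled_toy() -> tuple[StoichiometricModel, ToyGroundTruth]:
    """Nine-reaction fixture where an NADH balance couples growth to drains.

    Glucose (uptake ≤ 10) yields precursor ``p`` and NADH; NADH must be
    re-oxidized by oxygen-limited respiration (O₂ uptake ≤ 5), by an
    ethanol-like fermentation (2 NADH per precursor) or by a TAG-like branch
    (1 NADH per precursor).  Fermentation disposes of NADH at half the
    precursor cost, so the unique growth optimum runs fermentation at 5 and
    the TAG branch at 0, with growth μ = 7.5.  Knocking the fermentation
    reaction forces the TAG branch to carry the surplus: growth drops to 5.0
    and the optimistic TAG flux rises to 10.0 — the fixture's known best
    single knockout.

    Derivation (uptake g, fermentation x, TAG branch z):
    precursor balance 2g = 2μ + x + z; NADH balance 2g = 10 + 2x + z at the
    respiration cap; maximizing μ at g = 10 gives x = 5, z = 0, μ = 7.5.
    With x forced to 0: z = 2g − 10, μ = g − z/2 = 5; z is maximized at
    g = 10, giving z = 10.
    """
    model = StoichiometricModel(
        id="redox_coupled_toy",
        metabolites=[
            _met("glc", "glucose"),
            _met("o2", "oxygen"),
            _met("eth", "ethanol"),
            _met("p", "biomass precursor"),
            _met("nadh", "NADH"),
            _met("tag", "triacylglycerol"),
        ],
        reactions=[
            Reaction("EX_glc", "glucose exchange", {"glc": -1.0}, -10.0, 1000.0),
            Reaction("EX_o2", "oxygen exchange", {"o2": -1.0}, -5.0, 1000.0),
            Reaction("EX_eth", "ethanol exchange", {"eth": -1.0}, 0.0, 1000.0),
            Reaction(
                "GLY",
                "glycolysis (lumped)",
                {"glc": -1.0, "p": 2.0, "nadh": 2.0},
                0.0,
                1000.0,
                gene_association="SCO5426 or SCO2119 or SCO1214",
                subsystem="Glycolysis",
            ),
            Reaction(
                "RESP",
                "respiration (lumped)",
                {"nadh": -1.0, "o2": -0.5},
                0.0,
                1000.0,
                gene_association="SCO4562 and SCO4563",
                subsystem="Oxidative phosphorylation",
            ),
            Reaction(
                "FERM_E",
                "ethanol fermentation",
                {"p": -1.0, "nadh": -2.0, "eth": 1.0},
                0.0,
                1000.0,
                gene_association="SCO6788 or SCO1324",
                subsystem="Fermentation",
            ),
            Reaction(
                "FERM_T",
                "TAG-forming branch",
                {"p": -1.0, "nadh": -1.0, "tag": 1.0},
                0.0,
                1000.0,
                gene_association="SCO0958 and SCO1280",
                subsystem="Triacylglycerol biosynthesis",
            ),
            Reaction("DM_tag", "TAG demand", {"tag": -1.0}, 0.0, 1000.0),
            Reaction(
                "BIO",
                "biomass",
                {"p": -2.0},
                0.0,
                1000.0,
                objective_coefficient=1.0,
            ),
        ],
        objective_reaction_id="BIO",
    )
    truth = ToyGroundTruth(
        max_growth=7.5,
        optimistic_product_at_max_growth=0.0,
        best_single_knockout=(frozenset({"FERM_E"}), 10.0, 5.0),
        notes=(
            "hand LP: p-balance 2g = 2mu + x + z and nadh-balance 2g = 10 + 2x + z "
            "give x = 5, z = 0, mu = 7.5 at g = 10; knocking FERM_E forces z = 2g - 10, "
            "mu = 5, optimistic z = 10"
        ),
    )
    return model, truth


# branch uptake caps are drawn from this grid without replacement, so outer
# objectives of distinct knockout sets never tie
_BRANCH_CAP_GRID = [round(0.1 * k, 3) for k in range(1, 11)]


def make_tag_toy(
    n_extra_branches: int = 4, seed: int = 0
) -> tuple[StoichiometricModel, ToyGroundTruth]:
    """Randomized TAG-accumulation fixture with a β-oxidation-like recycle.

    Emulates the TAG neighborhood of a genome-scale actinomycete model:
    glucose catabolism produces acetyl-CoA and NADH; a reductive FAS-like
    reaction (2 acetyl-CoA + 2 NADH → acyl-CoA + CoA) feeds DAG assembly,
    and TAG synthesis itself is wired in by :func:`augment_tag_synthesis`
    (DGAT esterification plus a TAG demand).  The β-oxidation-like recycle
    ``BOX: acyl-CoA + CoA → 2 acetyl-CoA`` does *not* return the NADH spent
    by synthesis, so the FAS/BOX pair is a carbon-neutral redox sink — the
    growth optimum's preferred way to burn NADH beyond the oxygen-limited
    respiratory capacity.  Knocking BOX therefore forces surplus NADH
    through the TAG branch, making BOX the rank-1 single knockout for the
    TAG target by construction.

    ``n_extra_branches`` (0–10) adds byproduct drains
    ``BR_i: 0.5 acetyl-CoA + NADH → byp_i (+0.5 CoA)`` with seeded, distinct
    secretion caps; they are cheaper NADH sinks than TAG and become the
    partners in the best multi-knockout sets.

    The ground truth (growth optimum, optimistic TAG at that optimum, best
    single knockout) is computed at generation time by plain FBA and the
    brute-force oracle — never by the MILP engine.
    """
    if n_extra_branches < 0:
        raise ValueError("n_extra_branches must be ≥ 0")
    if n_extra_branches > len(_BRANCH_CAP_GRID):
        raise ValueError(f"n_extra_branches must be ≤ {len(_BRANCH_CAP_GRID)}")
    rng = random.Random(seed)
    caps = rng.sample(_BRANCH_CAP_GRID, n_extra_branches)

    metabolites = [
        _met("glc", "glucose"),
        _met("o2", "oxygen"),
        _met("accoa", "acetyl-CoA"),
        _met("coa", "coenzyme A"),
        _met("nadh", "NADH"),
        _met("acylcoa", "long-chain acyl-CoA"),
        _met("dag", "diacylglycerol"),
    ]
    reactions = [
        Reaction("EX_glc", "glucose exchange", {"glc": -1.0}, -10.0, 1000.0),
        Reaction("EX_o2", "oxygen exchange", {"o2": -1.0}, -4.0, 1000.0),
        Reaction(
            "GLY",
            "glycolysis + PDH (lumped)",
            {"glc": -1.0, "coa": -2.0, "accoa": 2.0, "nadh": 2.0},
            0.0,
            1000.0,
            gene_association="SCO5426 or SCO2119 or SCO1214",
            subsystem="Glycolysis",
        ),
        Reaction(
            "RESP",
            "respiration (lumped)",
            {"nadh": -1.0, "o2": -0.5},
            0.0,
            1000.0,
            gene_association="SCO4562 and SCO4563",
            subsystem="Oxidative phosphorylation",
        ),
        Reaction(
            "FAS",
            "fatty-acid synthesis (lumped)",
            {"accoa": -2.0, "nadh": -2.0, "acylcoa": 1.0, "coa": 1.0},
            0.0,
            1000.0,
            gene_association="SCO2388 and SCO1271",
            subsystem="Fatty acid biosynthesis",
        ),
        Reaction(
            "BOX",
            "beta-oxidation (lumped recycle)",
            {"acylcoa": -1.0, "coa": -1.0, "accoa": 2.0},
            0.0,
            1000.0,
            gene_association="SCO6788 or SCO1324 or SCO4502 or SCO6027",
            subsystem="Fatty acid degradation",
        ),
        Reaction(
            "DAGS",
            "DAG assembly (lumped)",
            {"acylcoa": -2.0, "dag": 1.0, "coa": 2.0},
            0.0,
            1000.0,
            gene_association="SCO1280",
            subsystem="Glycerolipid metabolism",
        ),
        Reaction(
            "BIO",
            "biomass",
            {"accoa": -2.0, "coa": 2.0},
            0.0,
            1000.0,
            objective_coefficient=1.0,
        ),
    ]
    for i, cap in enumerate(caps):
        byp = f"byp_{i}"
        metabolites.append(_met(byp, f"byproduct {i}"))
        reactions.append(
            Reaction(
                f"BR_{i}",
                f"byproduct branch {i}",
                {"accoa": -0.5, "nadh": -1.0, byp: 1.0, "coa": 0.5},
                0.0,
                1000.0,
                gene_association=f"SCO9{i:03d}",
                subsystem="Byproduct secretion",
            )
        )
        reactions.append(Reaction(f"EX_byp_{i}", f"byproduct {i} exchange", {byp: -1.0}, 0.0, cap))

    base = StoichiometricModel(
        id=f"tag_toy_s{seed}_b{n_extra_branches}",
        metabolites=metabolites,
        reactions=reactions,
        objective_reaction_id="BIO",
    )
    model, _delta = augment_tag_synthesis(
        base, dag_id="dag", acyl_coa_ids=["acylcoa"], tag_id="tag", coa_id="coa", add_demand=True
    )
    model.get_reaction("DGAT_acylcoa").gene_association = "SCO0958 or SCO1280"

    wt = solve_fba(model)
    optimistic = maximize_product_at_growth(model, "DM_tag", growth_fraction=1.0)
    config = OptKnockConfig(
        target_reaction_id="DM_tag",
        biomass_reaction_id="BIO",
        max_deletions=1,
        n_candidates=1,
    )
    oracle = brute_force_knockouts(model, config)
    best = None
    if oracle:
        top = oracle[0]
        best = (top.deleted_reaction_ids, top.outer_objective, top.inner_objective)
    truth = ToyGroundTruth(
        max_growth=float(wt.objective_value),
        optimistic_product_at_max_growth=float(optimistic.objective_value),
        best_single_knockout=best,
        notes=(
            "self-certifying fixture: max_growth from FBA, optimistic product from the "
            "lexicographic LP, best single knockout from the brute-force oracle, all at "
            "generation time"
        ),
        extra={"branch_caps": caps, "seed": seed},
    )
    return model, truth


def make_chemostat_fixture(
    dilution_rate: float,
    yield_coefficient: float,
    uptake_rate: float | None = None,
) -> tuple[StoichiometricModel, ChemostatCondition, ToyGroundTruth]:
    """Linear-chain model plus a chemostat condition that clamps uptake.

    The biomass yield per unit substrate uptake is ``yield_coefficient``, so
    clamping the exchange at ``uptake_rate`` (default: dilution_rate /
    yield_coefficient, i.e. a perfectly consistent measurement) forces
    μ_pred = yield_coefficient × uptake_rate.  The ground truth records the
    prediction and its relative error against the dilution rate D —
    the comparison used to validate a model against steady-state chemostat
    growth, where μ = D.
    """
    if dilution_rate <= 0:
        raise ValueError(f"dilution_rate must be positive, got {dilution_rate}")
    if yield_coefficient <= 0:
        raise ValueError(f"yield_coefficient must be positive, got {yield_coefficient}")
    if uptake_rate is None:
        uptake_rate = dilution_rate / yield_coefficient
    if uptake_rate < 0:
        raise ValueError(f"uptake_rate must be ≥ 0, got {uptake_rate}")

    model = StoichiometricModel(
        id="chemostat_chain",
        metabolites=[_met("s", "substrate", "e"), _met("x", "precursor")],
        reactions=[
            Reaction("EX_s", "substrate exchange", {"s": -1.0}, -1000.0, 1000.0),
            Reaction("UPT", "substrate assimilation", {"s": -1.0, "x": 1.0}, 0.0, 1000.0),
            Reaction(
                "BIO",
                "biomass",
                {"x": -1.0 / yield_coefficient},
                0.0,
                1000.0,
                objective_coefficient=1.0,
            ),
        ],
        objective_reaction_id="BIO",
    )
    condition = ChemostatCondition(
        dilution_rate=dilution_rate,
        exchange_constraints={"EX_s": (-uptake_rate, -uptake_rate)},
        description=(
            f"chemostat at D = {dilution_rate} /h with measured substrate uptake "
            f"{uptake_rate} mmol/gDCW/h"
        ),
    )
    mu_pred = yield_coefficient * uptake_rate
    truth = ToyGroundTruth(
        max_growth=mu_pred,
        notes="mu_pred = yield x uptake by conservation along the single path",
        extra={
            "predicted_growth": mu_pred,
            "relative_error": abs(mu_pred - dilution_rate) / dilution_rate,
        },
    )
    return model, condition, truth
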