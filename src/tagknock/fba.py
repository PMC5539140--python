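"""Linear-programming core: flux balance analysis and its companions.

FBA solves

    maximize    c·v
    subject to  S v = 0          (steady state)
                lb ≤ v ≤ ub      (capacity / thermodynamic direction)

where ``S`` is the stoichiometric matrix and ``v`` the flux vector
(mmol·gDCW⁻¹·h⁻¹).  The LP is solved with the HiGHS simplex/IPM backend
through ``scipy.optimize.linprog``; feasibility inside the solver is held to
1e-9 while all external comparisons use 1e-6.

Also provided: flux variability analysis (per-reaction flux ranges at a
fixed fraction of the optimum), lexicographic product maximization at fixed
growth (the optimistic scoring step used by knockout design), and
chemostat-constrained growth prediction, where measured exchange rates clamp
the exchange fluxes and the predicted growth rate μ is compared with the
dilution rate D (at steady state μ = D).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .core import StoichiometricModel, apply_knockouts

__all__ = [
    "FluxSolution",
    "FluxRange",
    "ChemostatCondition",
    "GrowthPrediction",
    "SolverError",
    "InfeasibleProblemError",
    "solve_fba",
    "flux_variability",
    "maximize_product_at_growth",
    "predict_chemostat_growth",
    "check_solution",
]

FEASIBILITY_TOL = 1e-9  # inside the solver
COMPARISON_TOL = 1e-6  # for all external checks

_SOLVER_OPTIONS = {
    "presolve": True,
    "primal_feasibility_tolerance": FEASIBILITY_TOL,
    "dual_feasibility_tolerance": FEASIBILITY_TOL,
}


class SolverError(RuntimeError):
    """Solver failed for a reason other than infeasibility/unboundedness."""


class InfeasibleProblemError(RuntimeError):
    """Raised when an operation requires a feasible base problem."""


@dataclass
class FluxSolution:
    status: str  # "optimal" | "infeasible" | "unbounded"
    objective_value: float | None = None
    fluxes: dict[str, float] = field(default_factory=dict)
    duals: dict[str, float] | None = None
    growth_optimum: float | None = None  # recorded by lexicographic solves

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class FluxRange:
    reaction_id: str
    min_flux: float
    max_flux: float


@dataclass
class ChemostatCondition:
    """Steady-state continuous-culture record used to constrain a model.

    ``dilution_rate`` is D in h⁻¹ (at steady state the specific growth rate
    equals D); ``exchange_constraints`` maps exchange reaction ids to
    measured (lower, upper) rate bounds in mmol·gDCW⁻¹·h⁻¹, negative for
    uptake.
    """

    dilution_rate: float
    exchange_constraints: dict[str, tuple[float, float]] = field(default_factory=dict)
    description: str = ""

    def __post_init__(self):
        if self.dilution_rate <= 0:
            raise ValueError(f"dilution_rate must be positive, got {self.dilution_rate}")
        for rid, (lo, hi) in self.exchange_constraints.items():
            if lo > hi:
                raise ValueError(f"constraint on {rid!r} has lower {lo} > upper {hi}")


@dataclass
class GrowthPrediction:
    predicted_growth: float  # μ_pred, h⁻¹
    dilution_rate: float  # D, h⁻¹
    relative_error: float  # |μ_pred − D| / D
    solution: FluxSolution


# ---------------------------------------------------------------------------


def _lp_arrays(model: StoichiometricModel):
    met_idx = model.metabolite_index()
    n = len(model.reactions)
    m = len(model.metabolites)
    rows, cols, vals = [], [], []
    for j, rxn in enumerate(model.reactions):
        for met_id, coeff in rxn.stoichiometry.items():
            rows.append(met_idx[met_id])
            cols.append(j)
            vals.append(coeff)
    S = sparse.csr_matrix((vals, (rows, cols)), shape=(m, n))
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    return S, bounds


_STATUS_MAP = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def _run_lp(c_min, S, bounds, A_ub=None, b_ub=None) -> tuple[str, object]:
    res = linprog(
        c_min,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=bounds,
        method="highs",
        options=_SOLVER_OPTIONS,
    )
    status = _STATUS_MAP.get(res.status)
    if status is None:
        raise SolverError(f"LP solver failure: {res.message}")
    return status, res


def solve_fba(
    model: StoichiometricModel,
    objective_reaction_id: str | None = None,
    direction: str = "max",
) -> FluxSolution:
    """Solve the FBA linear program for the model's (or an override) objective.

    Returns a :class:`FluxSolution`; degenerate alternate optima are not
    resolved — any optimal vertex is acceptable.  Metabolite duals (shadow
    prices of the steady-state constraints, for the maximization problem)
    are attached when the solve is optimal.
    """
    if direction not in ("max", "min"):
        raise ValueError(f"direction must be 'max' or 'min', got {direction!r}")
    obj_id = objective_reaction_id or model.objective_reaction_id
    j_obj = model.reaction_index().get(obj_id)
    if j_obj is None:
        raise ValueError(f"objective reaction {obj_id!r} not in model")

    S, bounds = _lp_arrays(model)
    c = np.zeros(len(model.reactions))
    c[j_obj] = 1.0
    sign = -1.0 if direction == "max" else 1.0
    status, res = _run_lp(sign * c, S, bounds)
    if status != "optimal":
        return FluxSolution(status=status)

    fluxes = {r.id: float(v) for r, v in zip(model.reactions, res.x)}
    duals = None
    if res.eqlin is not None and res.eqlin.marginals is not None:
        duals = {
            m.id: float(sign * y) for m, y in zip(model.metabolites, res.eqlin.marginals)
        }
    return FluxSolution(
        status="optimal",
        objective_value=float(res.x[j_obj]),
        fluxes=fluxes,
        duals=duals,
    )


def flux_variability(
    model: StoichiometricModel, fraction_of_optimum: float = 1.0
) -> list[FluxRange]:
    """Min/max flux per reaction with the objective held at a fraction of its optimum."""
    if not (0 < fraction_of_optimum <= 1):
        raise ValueError("fraction_of_optimum must be in (0, 1]")
    base = solve_fba(model)
    if not base.optimal:
        raise InfeasibleProblemError(f"base FBA is {base.status}; cannot run variability analysis")

    S, bounds = _lp_arrays(model)
    n = len(model.reactions)
    j_obj = model.reaction_index()[model.objective_reaction_id]
    # objective >= fraction * optimum, as -v_obj <= -fraction*optimum
    row = np.zeros((1, n))
    row[0, j_obj] = -1.0
    b_ub = np.array([-fraction_of_optimum * base.objective_value + FEASIBILITY_TOL])

    ranges = []
    for j, rxn in enumerate(model.reactions):
        c = np.zeros(n)
        c[j] = 1.0
        lo_status, lo = _run_lp(c, S, bounds, A_ub=row, b_ub=b_ub)
        hi_status, hi = _run_lp(-c, S, bounds, A_ub=row, b_ub=b_ub)
        if lo_status != "optimal" or hi_status != "optimal":
            raise InfeasibleProblemError(
                f"variability subproblem for {rxn.id!r} ended {lo_status}/{hi_status}"
            )
        ranges.append(FluxRange(rxn.id, float(lo.x[j]), float(hi.x[j])))
    return ranges


def maximize_product_at_growth(
    model: StoichiometricModel,
    product_reaction_id: str,
    growth_fraction: float = 1.0,
) -> FluxSolution:
    """Lexicographic LP: first maximize growth, then the product at that growth.

    Step 1 maximizes the biomass objective, giving μ*.  Step 2 maximizes the
    product flux subject to ``v_biomass ≥ growth_fraction × μ*``.  This is
    the *optimistic* scoring convention: among alternate growth-optimal flux
    states the one most favorable to the product is credited.  The returned
    solution is from step 2, with μ* recorded as ``growth_optimum``.
    """
    if not (0 <= growth_fraction <= 1):
        raise ValueError("growth_fraction must be in [0, 1]")
    ridx = model.reaction_index()
    if product_reaction_id not in ridx:
        raise ValueError(f"product reaction {product_reaction_id!r} not in model")
    j_bio = ridx[model.objective_reaction_id]
    j_prod = ridx[product_reaction_id]

    step1 = solve_fba(model)
    if not step1.optimal:
        return step1
    mu_star = step1.objective_value

    S, bounds = _lp_arrays(model)
    n = len(model.reactions)
    c = np.zeros(n)
    c[j_prod] = 1.0
    row = np.zeros((1, n))
    row[0, j_bio] = -1.0
    b_ub = np.array([-growth_fraction * mu_star + FEASIBILITY_TOL])
    status, res = _run_lp(-c, S, bounds, A_ub=row, b_ub=b_ub)
    if status != "optimal":
        return FluxSolution(status=status, growth_optimum=mu_star)
    fluxes = {r.id: float(v) for r, v in zip(model.reactions, res.x)}
    return FluxSolution(
        status="optimal",
        objective_value=float(res.x[j_prod]),
        fluxes=fluxes,
        growth_optimum=float(mu_star),
    )


def predict_chemostat_growth(
    model: StoichiometricModel, condition: ChemostatCondition
) -> GrowthPrediction:
    """Clamp measured exchange rates and predict the growth rate.

    Each constrained exchange reaction's bounds are replaced by the measured
    (lower, upper) interval; biomass is then maximized.  The prediction is
    compared against the dilution rate D through
    ``relative_error = |μ_pred − D| / D``.
    """
    clamped = model.copy()
    for rid, (lo, hi) in condition.exchange_constraints.items():
        rxn = clamped.get_reaction(rid)  # ModelError on unknown id
        rxn.lower_bound, rxn.upper_bound = lo, hi
    sol = solve_fba(clamped)
    if not sol.optimal:
        binding = ", ".join(sorted(condition.exchange_constraints))
        raise InfeasibleProblemError(
            f"chemostat-constrained FBA is {sol.status}; clamped exchanges: {binding}"
        )
    mu_pred = sol.objective_value
    rel_err = abs(mu_pred - condition.dilution_rate) / condition.dilution_rate
    return GrowthPrediction(
        predicted_growth=float(mu_pred),
        dilution_rate=condition.dilution_rate,
        relative_error=float(rel_err),
        solution=sol,
    )


def check_solution(
    model: StoichiometricModel, solution: FluxSolution, tol: float = COMPARISON_TOL
) -> bool:
    """Independent feasibility certificate: |S v| ≤ tol row-wise, bounds
    respected within tol, and the stored objective equals the objective flux."""
    if not solution.optimal:
        return False
    v = np.array([solution.fluxes[r.id] for r in model.reactions])
    S, _bounds = _lp_arrays(model)
    if np.max(np.abs(S @ v)) > tol:
        return False
    for rxn, vj in zip(model.reactions, v):
        if vj < rxn.lower_bound - tol or vj > rxn.upper_bound + tol:
            return False
    if solution.objective_value is None:
        return False
    if solution.growth_optimum is None:
        # plain FBA: the stored objective is the model-objective flux
        j = model.reaction_index()[model.objective_reaction_id]
        if abs(solution.objective_value - v[j]) > tol:
            return False
    return True


def knockout_growth(model: StoichiometricModel, reaction_ids) -> float:
    """Convenience: FBA growth optimum after deleting the given reactions."""
    sol = solve_fba(apply_knockouts(model, reaction_ids))
    return sol.objective_value if sol.optimal else 0.0
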