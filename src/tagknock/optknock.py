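"""Bilevel knockout design (OptKnock) via a strong-duality MILP, plus a
brute-force oracle.

The bilevel program chooses at most K reaction deletions (binary y_j, 1 =
reaction active) to maximize an engineering objective (e.g. flux into a TAG
demand) while the *inner* cell maximizes growth:

    outer:  max  v_target
            s.t. Σ_j (1 − y_j) ≤ K         over knockable j
    inner:  max  v_biomass
            s.t. S v = 0,  y_j·lb_j ≤ v_j ≤ y_j·ub_j

The inner LP is collapsed into the outer problem by imposing, jointly, its
primal feasibility, its dual feasibility, and the strong-duality equality
(primal objective = dual objective).  Products of dual variables with the
binaries are linearized with big-M constraints.  Because the single-level
problem optimizes target and growth jointly, inner alternate optima are
resolved *optimistically* — the growth-optimal flux state most favorable to
the target is the one credited, which is also how the brute-force oracle
scores deletion sets (lexicographic growth-then-product LP).

Candidates are enumerated by re-solving under *integer cuts*
``Σ_{j∈deleted} y_j ≥ 1``, which forbid each found deletion set and all of
its supersets, yielding a ranked list of mechanistically distinct
strategies.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .core import StoichiometricModel, apply_knockouts, genes_for_candidate
from .fba import COMPARISON_TOL, SolverError, maximize_product_at_growth, solve_fba

__all__ = [
    "OptKnockConfig",
    "KnockoutCandidate",
    "OptKnockMILP",
    "select_knockable",
    "formulate_optknock",
    "enumerate_candidates",
    "brute_force_knockouts",
    "verify_candidate",
]

# Tiny objective perturbations that make the MILP's choice among ties
# deterministic: prefer fewer deletions, then lexicographically smaller
# deleted-reaction-id sets.  Far below any meaningful flux difference.
_EPS_CARDINALITY = 1e-4
_EPS_LEX = 5e-5

_BRUTE_FORCE_GUARD = 20_000


@dataclass
class OptKnockConfig:
    target_reaction_id: str
    biomass_reaction_id: str
    max_deletions: int = 1  # K
    n_candidates: int = 10
    min_biomass_fraction: float = 0.1
    big_m: float | None = None  # None → per-reaction max(|lb|, |ub|, default_bound)
    knockable_reaction_ids: set[str] | None = None

    def __post_init__(self):
        if self.target_reaction_id == self.biomass_reaction_id:
            raise ValueError("target and biomass reactions must differ")
        if self.n_candidates < 1:
            raise ValueError("n_candidates must be ≥ 1")
        if self.max_deletions < 0:
            raise ValueError("max_deletions must be ≥ 0")
        if not (0 <= self.min_biomass_fraction <= 1):
            raise ValueError("min_biomass_fraction must be in [0, 1]")


@dataclass
class KnockoutCandidate:
    deleted_reaction_ids: frozenset[str]
    outer_objective: float  # target flux under optimistic inner optimum
    inner_objective: float  # growth optimum of the knocked model
    verified: bool = False
    genes: dict[str, list[str]] = field(default_factory=dict)
    duality_gap: float | None = None  # |inner primal − inner dual| at the MILP solution
    diagnostic: str = ""


def select_knockable(model: StoichiometricModel, config: OptKnockConfig) -> set[str]:
    """Deletion candidates: all reactions except boundary reactions, the
    biomass reaction, and the target reaction — unless the config names an
    explicit set."""
    if config.knockable_reaction_ids is not None:
        for rid in config.knockable_reaction_ids:
            model.get_reaction(rid)
        return set(config.knockable_reaction_ids)
    knockable = {
        r.id
        for r in model.reactions
        if not r.is_boundary
        and r.id != config.biomass_reaction_id
        and r.id != config.target_reaction_id
    }
    if not knockable:
        raise ValueError("no knockable reactions remain after exclusions")
    return knockable


# ---------------------------------------------------------------------------
# MILP formulation
# ---------------------------------------------------------------------------


@dataclass
class OptKnockMILP:
    """Inspectable single-level reformulation.

    Variable layout (columns of ``constraints`` / entries of ``objective``):
    fluxes v (n), steady-state duals λ (m, free), upper-bound duals μ (n ≥ 0),
    lower-bound duals γ (n ≥ 0), binaries y (one per knockable reaction,
    sorted by id), then linearization products w⁺ = y·μ and w⁻ = y·γ for the
    knockable columns.  The objective (to maximize) is v_target plus the
    deterministic tie-break perturbation on y.
    """

    model_id: str
    reaction_ids: list[str]
    metabolite_ids: list[str]
    knockable_ids: list[str]  # sorted; defines the y order
    objective: np.ndarray  # maximize objective · x
    integrality: np.ndarray
    var_lb: np.ndarray
    var_ub: np.ndarray
    A: sparse.csr_matrix
    row_lb: np.ndarray
    row_ub: np.ndarray
    wt_growth: float
    config: OptKnockConfig
    # index helpers
    n_reactions: int = 0
    n_metabolites: int = 0

    def column(self, kind: str, key: str) -> int:
        n, m, nk = self.n_reactions, self.n_metabolites, len(self.knockable_ids)
        if kind == "v":
            return self.reaction_ids.index(key)
        if kind == "lambda":
            return n + self.metabolite_ids.index(key)
        if kind == "mu":
            return n + m + self.reaction_ids.index(key)
        if kind == "gamma":
            return 2 * n + m + self.reaction_ids.index(key)
        if kind == "y":
            return 3 * n + m + self.knockable_ids.index(key)
        if kind == "wplus":
            return 3 * n + m + nk + self.knockable_ids.index(key)
        if kind == "wminus":
            return 3 * n + m + 2 * nk + self.knockable_ids.index(key)
        raise KeyError(kind)

    @property
    def n_variables(self) -> int:
        return self.objective.size


def formulate_optknock(model: StoichiometricModel, config: OptKnockConfig) -> OptKnockMILP:
    """Build the strong-duality single-level MILP for the bilevel program."""
    ridx = model.reaction_index()
    if config.target_reaction_id not in ridx:
        raise ValueError(f"target reaction {config.target_reaction_id!r} not in model")
    if config.biomass_reaction_id not in ridx:
        raise ValueError(f"biomass reaction {config.biomass_reaction_id!r} not in model")

    for rxn in model.reactions:
        if not np.isfinite(rxn.lower_bound) or not np.isfinite(rxn.upper_bound):
            raise ValueError(
                f"reaction {rxn.id!r} has a non-finite bound; cap unbounded reactions "
                f"at the model default_bound before formulating the MILP"
            )

    knockable = sorted(select_knockable(model, config))
    n = len(model.reactions)
    m = len(model.metabolites)
    nk = len(knockable)
    knock_set = set(knockable)

    wt = solve_fba(model, objective_reaction_id=config.biomass_reaction_id)
    if not wt.optimal:
        raise ValueError(f"wild-type FBA is {wt.status}; cannot anchor the viability constraint")
    mu_wt = wt.objective_value

    def big_m_for(rxn) -> float:
        if config.big_m is not None:
            return config.big_m
        return max(abs(rxn.lower_bound), abs(rxn.upper_bound), model.default_bound)

    M = {r.id: big_m_for(r) for r in model.reactions}

    # --- variables: v(n) λ(m) μ(n) γ(n) y(nk) w+(nk) w-(nk)
    nvar = 3 * n + m + 3 * nk
    off_v, off_l, off_mu, off_g = 0, n, n + m, 2 * n + m
    off_y, off_wp, off_wm = 3 * n + m, 3 * n + m + nk, 3 * n + m + 2 * nk

    var_lb = np.zeros(nvar)
    var_ub = np.zeros(nvar)
    for j, rxn in enumerate(model.reactions):
        if rxn.id in knock_set:
            var_lb[off_v + j] = min(rxn.lower_bound, 0.0)
            var_ub[off_v + j] = max(rxn.upper_bound, 0.0)
        else:
            var_lb[off_v + j] = rxn.lower_bound
            var_ub[off_v + j] = rxn.upper_bound
    var_lb[off_l : off_l + m] = -np.inf
    var_ub[off_l : off_l + m] = np.inf
    for j, rxn in enumerate(model.reactions):
        var_lb[off_mu + j] = 0.0
        var_ub[off_mu + j] = M[rxn.id]
        var_lb[off_g + j] = 0.0
        var_ub[off_g + j] = M[rxn.id]
    var_lb[off_y : off_y + nk] = 0.0
    var_ub[off_y : off_y + nk] = 1.0
    for k, rid in enumerate(knockable):
        var_lb[off_wp + k] = 0.0
        var_ub[off_wp + k] = M[rid]
        var_lb[off_wm + k] = 0.0
        var_ub[off_wm + k] = M[rid]

    integrality = np.zeros(nvar)
    integrality[off_y : off_y + nk] = 1

    rows, cols, vals = [], [], []
    row_lb: list[float] = []
    row_ub: list[float] = []

    def add_row(entries: dict[int, float], lo: float, hi: float):
        r = len(row_lb)
        for col, val in entries.items():
            rows.append(r)
            cols.append(col)
            vals.append(val)
        row_lb.append(lo)
        row_ub.append(hi)

    met_idx = model.metabolite_index()

    # (a) steady state: S v = 0
    srows: list[dict[int, float]] = [dict() for _ in range(m)]
    for j, rxn in enumerate(model.reactions):
        for met_id, coeff in rxn.stoichiometry.items():
            srows[met_idx[met_id]][off_v + j] = coeff
    for entries in srows:
        add_row(entries, 0.0, 0.0)

    # (b) knockout-switched bounds: y_j lb_j ≤ v_j ≤ y_j ub_j
    for k, rid in enumerate(knockable):
        j = ridx[rid]
        rxn = model.reactions[j]
        add_row({off_v + j: 1.0, off_y + k: -rxn.upper_bound}, -np.inf, 0.0)
        add_row({off_v + j: -1.0, off_y + k: rxn.lower_bound}, -np.inf, 0.0)

    # (c) inner dual feasibility: Sᵀλ + μ − γ = c_inner
    j_bio = ridx[config.biomass_reaction_id]
    for j, rxn in enumerate(model.reactions):
        entries = {off_mu + j: 1.0, off_g + j: -1.0}
        for met_id, coeff in rxn.stoichiometry.items():
            entries[off_l + met_idx[met_id]] = coeff
        rhs = 1.0 if j == j_bio else 0.0
        add_row(entries, rhs, rhs)

    # (d) strong duality: c_inner·v = Σ ub_j y_j μ_j − Σ lb_j y_j γ_j,
    #     with y_j μ_j → w⁺ and y_j γ_j → w⁻ for knockable columns
    sd: dict[int, float] = {off_v + j_bio: 1.0}
    for j, rxn in enumerate(model.reactions):
        if rxn.id in knock_set:
            k = knockable.index(rxn.id)
            sd[off_wp + k] = sd.get(off_wp + k, 0.0) - rxn.upper_bound
            sd[off_wm + k] = sd.get(off_wm + k, 0.0) + rxn.lower_bound
        else:
            sd[off_mu + j] = sd.get(off_mu + j, 0.0) - rxn.upper_bound
            sd[off_g + j] = sd.get(off_g + j, 0.0) + rxn.lower_bound
    add_row(sd, 0.0, 0.0)

    # (e) big-M linearization of w⁺ = y μ and w⁻ = y γ
    for k, rid in enumerate(knockable):
        j = ridx[rid]
        Mk = M[rid]
        # w ≤ M y ; w ≤ μ ; w ≥ μ − M(1 − y)
        add_row({off_wp + k: 1.0, off_y + k: -Mk}, -np.inf, 0.0)
        add_row({off_wp + k: 1.0, off_mu + j: -1.0}, -np.inf, 0.0)
        add_row({off_mu + j: 1.0, off_wp + k: -1.0, off_y + k: Mk}, -np.inf, Mk)
        add_row({off_wm + k: 1.0, off_y + k: -Mk}, -np.inf, 0.0)
        add_row({off_wm + k: 1.0, off_g + j: -1.0}, -np.inf, 0.0)
        add_row({off_g + j: 1.0, off_wm + k: -1.0, off_y + k: Mk}, -np.inf, Mk)

    # (f) deletion budget: Σ y ≥ nk − K
    add_row({off_y + k: 1.0 for k in range(nk)}, float(nk - config.max_deletions), np.inf)

    # (g) viability floor from the wild-type optimum
    add_row({off_v + j_bio: 1.0}, config.min_biomass_fraction * mu_wt, np.inf)

    objective = np.zeros(nvar)
    objective[off_v + ridx[config.target_reaction_id]] = 1.0
    for k in range(nk):
        objective[off_y + k] = _EPS_CARDINALITY - _EPS_LEX * (2.0 ** (-min(k, 50)))

    A = sparse.csr_matrix((vals, (rows, cols)), shape=(len(row_lb), nvar))
    milp_obj = OptKnockMILP(
        model_id=model.id,
        reaction_ids=[r.id for r in model.reactions],
        metabolite_ids=[mt.id for mt in model.metabolites],
        knockable_ids=knockable,
        objective=objective,
        integrality=integrality,
        var_lb=var_lb,
        var_ub=var_ub,
        A=A,
        row_lb=np.array(row_lb),
        row_ub=np.array(row_ub),
        wt_growth=float(mu_wt),
        config=config,
        n_reactions=n,
        n_metabolites=m,
    )
    return milp_obj


def _solve_milp(problem: OptKnockMILP, extra_cuts: list[dict[int, float]]):
    """Solve the MILP with additional ≥1 cut rows; returns (status, x)."""
    A = problem.A
    row_lb = problem.row_lb
    row_ub = problem.row_ub
    if extra_cuts:
        rows, cols, vals = [], [], []
        for r, cut in enumerate(extra_cuts):
            for col, val in cut.items():
                rows.append(r)
                cols.append(col)
                vals.append(val)
        A_cut = sparse.csr_matrix((vals, (rows, cols)), shape=(len(extra_cuts), problem.n_variables))
        A = sparse.vstack([A, A_cut], format="csr")
        row_lb = np.concatenate([row_lb, np.ones(len(extra_cuts))])
        row_ub = np.concatenate([row_ub, np.full(len(extra_cuts), np.inf)])

    res = milp(
        c=-problem.objective,  # milp minimizes
        constraints=LinearConstraint(A, row_lb, row_ub),
        integrality=problem.integrality,
        bounds=Bounds(problem.var_lb, problem.var_ub),
        options={"mip_rel_gap": 0.0},
    )
    if res.status == 0:
        return "optimal", res.x
    if res.status == 2:
        return "infeasible", None
    if res.status == 3:
        return "unbounded", None
    raise SolverError(f"MILP solver failure (status {res.status}): {res.message}")


def _inner_duality_gap(problem: OptKnockMILP, x: np.ndarray, model: StoichiometricModel) -> float:
    """|inner primal objective − inner dual objective| at a MILP point."""
    ridx = model.reaction_index()
    primal = x[problem.column("v", problem.config.biomass_reaction_id)]
    dual = 0.0
    knock_set = set(problem.knockable_ids)
    for rxn in model.reactions:
        j = ridx[rxn.id]
        if rxn.id in knock_set:
            k = problem.knockable_ids.index(rxn.id)
            wp = x[problem.column("wplus", rxn.id)]
            wm = x[problem.column("wminus", rxn.id)]
            dual += rxn.upper_bound * wp - rxn.lower_bound * wm
        else:
            mu = x[problem.column("mu", rxn.id)]
            ga = x[problem.column("gamma", rxn.id)]
            dual += rxn.upper_bound * mu - rxn.lower_bound * ga
    return abs(primal - dual)


# ---------------------------------------------------------------------------
# candidate scoring, enumeration, verification
# ---------------------------------------------------------------------------


def _wild_type_growth(model: StoichiometricModel, config: OptKnockConfig) -> float:
    wt = solve_fba(model, objective_reaction_id=config.biomass_reaction_id)
    if not wt.optimal:
        raise ValueError(f"wild-type FBA is {wt.status}")
    return float(wt.objective_value)


def _score_deletion_set(
    model: StoichiometricModel,
    config: OptKnockConfig,
    deleted: frozenset[str],
    mu_wt: float,
) -> tuple[float, float] | None:
    """Optimistic (outer, inner) objectives for a deletion set, or None if
    the knocked model cannot sustain the viability floor."""
    knocked = apply_knockouts(model, deleted)
    knocked.objective_reaction_id = config.biomass_reaction_id
    prod = maximize_product_at_growth(knocked, config.target_reaction_id, growth_fraction=1.0)
    if not prod.optimal:
        return None
    mu = prod.growth_optimum
    if mu < config.min_biomass_fraction * mu_wt - COMPARISON_TOL:
        return None
    return float(prod.objective_value), float(mu)


def _rank_key(candidate: KnockoutCandidate):
    return (
        -candidate.outer_objective,
        len(candidate.deleted_reaction_ids),
        tuple(sorted(candidate.deleted_reaction_ids)),
    )


def verify_candidate(
    model: StoichiometricModel, config: OptKnockConfig, candidate: KnockoutCandidate
) -> KnockoutCandidate:
    """Re-simulate a candidate and flag whether its objectives reproduce.

    The deletion set is re-applied, growth re-optimized, and the target
    re-maximized at the knocked model's own growth optimum; ``verified`` is
    set iff both recomputed objectives match the stored ones within 1e-6.
    """
    knocked = apply_knockouts(model, candidate.deleted_reaction_ids)
    knocked.objective_reaction_id = config.biomass_reaction_id
    prod = maximize_product_at_growth(knocked, config.target_reaction_id, growth_fraction=1.0)
    if not prod.optimal:
        return replace(candidate, verified=False, diagnostic=f"re-simulated scoring LP is {prod.status}")
    ok_outer = abs(prod.objective_value - candidate.outer_objective) <= COMPARISON_TOL
    ok_inner = abs(prod.growth_optimum - candidate.inner_objective) <= COMPARISON_TOL
    diagnostic = ""
    if not ok_outer:
        diagnostic = (
            f"outer objective mismatch: stored {candidate.outer_objective:.6f}, "
            f"recomputed {prod.objective_value:.6f}"
        )
    elif not ok_inner:
        diagnostic = (
            f"inner objective mismatch: stored {candidate.inner_objective:.6f}, "
            f"recomputed {prod.growth_optimum:.6f}"
        )
    return replace(candidate, verified=ok_outer and ok_inner, diagnostic=diagnostic)


def _wild_type_candidate(model: StoichiometricModel, config: OptKnockConfig) -> KnockoutCandidate:
    scored = model.copy()
    scored.objective_reaction_id = config.biomass_reaction_id
    prod = maximize_product_at_growth(scored, config.target_reaction_id, growth_fraction=1.0)
    return KnockoutCandidate(
        deleted_reaction_ids=frozenset(),
        outer_objective=float(prod.objective_value),
        inner_objective=float(prod.growth_optimum),
        genes={},
    )


def enumerate_candidates(
    model: StoichiometricModel, config: OptKnockConfig
) -> list[KnockoutCandidate]:
    """Ranked knockout candidates from the MILP with integer cuts.

    Solving, recording, cutting and re-solving continues until
    ``n_candidates`` candidates are found, the MILP goes infeasible, or the
    best remaining outer objective drops to ≤ 1e-6.  Every candidate is
    re-simulated through :func:`verify_candidate`.  Ranking: outer objective
    descending, then fewer deletions, then lexicographic deleted-set ids —
    the MILP's tie-break perturbation enforces the same order.
    """
    if config.max_deletions == 0:
        cand = _wild_type_candidate(model, config)
        return [verify_candidate(model, config, cand)]

    problem = formulate_optknock(model, config)
    candidates: list[KnockoutCandidate] = []
    cuts: list[dict[int, float]] = []

    while len(candidates) < config.n_candidates:
        status, x = _solve_milp(problem, cuts)
        if status != "optimal":
            break
        deleted = frozenset(
            rid for rid in problem.knockable_ids if x[problem.column("y", rid)] < 0.5
        )
        gap = _inner_duality_gap(problem, x, model)
        milp_outer = float(x[problem.column("v", config.target_reaction_id)])
        if milp_outer <= COMPARISON_TOL:
            break
        if not deleted:
            # wild type already achieves the optimum; nothing to cut on
            break
        score = _score_deletion_set(model, config, deleted, problem.wt_growth)
        if score is None:
            # numerically viable in the MILP but not on re-simulation; cut and move on
            cuts.append({problem.column("y", rid): 1.0 for rid in deleted})
            continue
        outer, inner = score
        cand = KnockoutCandidate(
            deleted_reaction_ids=deleted,
            outer_objective=outer,
            inner_objective=inner,
            genes=genes_for_candidate(model, deleted),
            duality_gap=gap,
        )
        candidates.append(verify_candidate(model, config, cand))
        cuts.append({problem.column("y", rid): 1.0 for rid in deleted})

    candidates.sort(key=_rank_key)
    return candidates


def brute_force_knockouts(
    model: StoichiometricModel, config: OptKnockConfig
) -> list[KnockoutCandidate]:
    """Independent oracle: exhaustively score every deletion set of size ≤ K.

    Sets are scored exactly as the MILP scores them (lexicographic LP with
    growth_fraction 1.0 on the knocked model, subject to the viability
    floor), filtered to outer objective > 1e-6, ranked, and pruned so that
    no returned set is a superset of a better-ranked one — mirroring the
    integer-cut semantics of :func:`enumerate_candidates`.
    """
    if config.max_deletions == 0:
        cand = _wild_type_candidate(model, config)
        return [verify_candidate(model, config, cand)]

    knockable = sorted(select_knockable(model, config))
    total = sum(
        _n_choose_k(len(knockable), k) for k in range(1, config.max_deletions + 1)
    )
    if total > _BRUTE_FORCE_GUARD:
        raise ValueError(
            f"{total} deletion sets exceed the brute-force guard of {_BRUTE_FORCE_GUARD}; "
            f"pass an explicit knockable_reaction_ids set"
        )

    mu_wt = _wild_type_growth(model, config)
    scored: list[KnockoutCandidate] = []
    for k in range(1, config.max_deletions + 1):
        for combo in itertools.combinations(knockable, k):
            deleted = frozenset(combo)
            score = _score_deletion_set(model, config, deleted, mu_wt)
            if score is None:
                continue
            outer, inner = score
            if outer <= COMPARISON_TOL:
                continue
            scored.append(
                KnockoutCandidate(
                    deleted_reaction_ids=deleted,
                    outer_objective=outer,
                    inner_objective=inner,
                    genes=genes_for_candidate(model, deleted),
                )
            )

    scored.sort(key=_rank_key)
    kept: list[KnockoutCandidate] = []
    for cand in scored:
        if any(cand.deleted_reaction_ids > prev.deleted_reaction_ids for prev in kept):
            continue
        kept.append(verify_candidate(model, config, cand))
        if len(kept) >= config.n_candidates:
            break
    return kept


def _n_choose_k(n: int, k: int) -> int:
    import math

    return math.comb(n, k)


def export_lp_text(problem: OptKnockMILP) -> str:
    """Rough LP-format dump of the MILP for debugging."""
    lines = [f"\\ OptKnock MILP for model {problem.model_id}", "Maximize", " obj:"]
    terms = [
        f" {c:+.6g} x{i}" for i, c in enumerate(problem.objective) if c != 0.0
    ]
    lines.append("  " + " ".join(terms))
    lines.append("Subject To")
    A = problem.A.tocoo()
    by_row: dict[int, list[str]] = {}
    for r, c, v in zip(A.row, A.col, A.data):
        by_row.setdefault(r, []).append(f"{v:+.6g} x{c}")
    for r in range(problem.A.shape[0]):
        expr = " ".join(by_row.get(r, []))
        lo, hi = problem.row_lb[r], problem.row_ub[r]
        if lo == hi:
            lines.append(f" c{r}: {expr} = {lo:.6g}")
        elif np.isfinite(hi) and not np.isfinite(lo):
            lines.append(f" c{r}: {expr} <= {hi:.6g}")
        elif np.isfinite(lo) and not np.isfinite(hi):
            lines.append(f" c{r}: {expr} >= {lo:.6g}")
        else:
            lines.append(f" c{r}: {lo:.6g} <= {expr} <= {hi:.6g}")
    lines.append("Bounds")
    for i in range(problem.n_variables):
        lines.append(f" {problem.var_lb[i]:.6g} <= x{i} <= {problem.var_ub[i]:.6g}")
    lines.append("Binaries")
    lines.append(" " + " ".join(f"x{i}" for i, z in enumerate(problem.integrality) if z))
    lines.append("End")
    return "\n".join(lines)
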