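"""Domain types and model-editing operations for constraint-based models.

The central object is :class:`StoichiometricModel`: an ordered collection of
metabolites and reactions from which the stoichiometric matrix ``S`` (one row
per metabolite, one column per reaction, signed coefficients) is built.
Fluxes are in mmol·gDCW⁻¹·h⁻¹ by convention; the biomass reaction's flux is
the specific growth rate μ (h⁻¹).

Model edits used by the triacylglycerol (TAG) workflow live here:

* :func:`augment_tag_synthesis` adds acyl-CoA–dependent TAG esterification
  (DGAT-style, ``DAG + acyl-CoA → TAG + CoA``) to a model whose TAG synthesis
  would otherwise be absent or acyl-carrier-bound, leaving the biomass
  equation untouched.
* :func:`apply_knockouts` zeroes reaction bounds to simulate deletions.
* GPR helpers map reaction deletions back to candidate genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .gpr import GPRParseError, evaluate_gpr as _evaluate_gpr, gpr_genes, normalize_gpr

__all__ = [
    "Metabolite",
    "Reaction",
    "StoichiometricModel",
    "ModelDelta",
    "ValidationIssue",
    "ValidationReport",
    "ModelError",
    "validate_model",
    "augment_tag_synthesis",
    "revert_delta",
    "apply_knockouts",
    "evaluate_gpr",
    "genes_for_candidate",
]

_FLOAT_TOL = 1e-12


class ModelError(ValueError):
    """Raised for structurally invalid model operations (unknown ids, clashes)."""


def _close(a: float, b: float) -> bool:
    return math.isclose(a, b, rel_tol=_FLOAT_TOL, abs_tol=_FLOAT_TOL)


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None
    charge: int | None = None

    def copy(self) -> "Metabolite":
        return replace(self)


@dataclass(eq=False)
class Reaction:
    """A reaction column: signed stoichiometry, flux bounds, gene rule.

    Negative stoichiometric coefficients consume, positive produce.  A
    *boundary* reaction (exchange/demand/sink) touches a single metabolite
    and connects the network to the environment; by convention its negative
    flux is uptake and positive flux is secretion.
    """

    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gene_association: str | None = None
    objective_coefficient: float = 0.0
    subsystem: str | None = None

    @property
    def is_boundary(self) -> bool:
        return len(self.stoichiometry) == 1

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))

    def __eq__(self, other) -> bool:
        if not isinstance(other, Reaction):
            return NotImplemented
        if (self.id, self.name, self.subsystem) != (other.id, other.name, other.subsystem):
            return False
        if set(self.stoichiometry) != set(other.stoichiometry):
            return False
        if not all(_close(v, other.stoichiometry[k]) for k, v in self.stoichiometry.items()):
            return False
        if not (
            _close(self.lower_bound, other.lower_bound)
            and _close(self.upper_bound, other.upper_bound)
            and _close(self.objective_coefficient, other.objective_coefficient)
        ):
            return False
        try:
            return normalize_gpr(self.gene_association) == normalize_gpr(other.gene_association)
        except GPRParseError:
            return self.gene_association == other.gene_association


@dataclass(eq=False)
class StoichiometricModel:
    id: str
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    objective_reaction_id: str = ""
    default_bound: float = 1000.0

    # -- lookups -------------------------------------------------------

    def metabolite_index(self) -> dict[str, int]:
        return {m.id: i for i, m in enumerate(self.metabolites)}

    def reaction_index(self) -> dict[str, int]:
        return {r.id: i for i, r in enumerate(self.reactions)}

    def get_reaction(self, reaction_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == reaction_id:
                return r
        raise ModelError(f"unknown reaction id {reaction_id!r} in model {self.id!r}")

    def get_metabolite(self, metabolite_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == metabolite_id:
                return m
        raise ModelError(f"unknown metabolite id {metabolite_id!r} in model {self.id!r}")

    def has_metabolite(self, metabolite_id: str) -> bool:
        return any(m.id == metabolite_id for m in self.metabolites)

    def has_reaction(self, reaction_id: str) -> bool:
        return any(r.id == reaction_id for r in self.reactions)

    @property
    def objective_reaction(self) -> Reaction:
        return self.get_reaction(self.objective_reaction_id)

    def stoichiometric_matrix(self):
        """Dense S as a numpy array plus row/column id orderings."""
        import numpy as np

        met_idx = self.metabolite_index()
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met_id, coeff in rxn.stoichiometry.items():
                S[met_idx[met_id], j] = coeff
        return S, [m.id for m in self.metabolites], [r.id for r in self.reactions]

    def copy(self) -> "StoichiometricModel":
        return StoichiometricModel(
            id=self.id,
            metabolites=[m.copy() for m in self.metabolites],
            reactions=[r.copy() for r in self.reactions],
            objective_reaction_id=self.objective_reaction_id,
            default_bound=self.default_bound,
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, StoichiometricModel):
            return NotImplemented
        return (
            self.id == other.id
            and self.objective_reaction_id == other.objective_reaction_id
            and _close(self.default_bound, other.default_bound)
            and self.metabolites == other.metabolites
            and self.reactions == other.reactions
        )


@dataclass
class ModelDelta:
    """Auditable record of a model edit; applying then reverting restores
    the source model exactly."""

    added_reactions: list[Reaction] = field(default_factory=list)
    added_metabolites: list[Metabolite] = field(default_factory=list)
    modified_bounds: dict[str, tuple[float, float, float, float]] = field(default_factory=dict)
    note: str = ""


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationIssue:
    severity: str  # "error" | "warning"
    target_id: str
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]


def validate_model(model: StoichiometricModel) -> ValidationReport:
    """Structural validation; reports problems, never raises or mutates."""
    issues: list[ValidationIssue] = []

    seen_mets: set[str] = set()
    for met in model.metabolites:
        if not met.id:
            issues.append(ValidationIssue("error", "", "metabolite with empty id"))
            continue
        if met.id in seen_mets:
            issues.append(ValidationIssue("error", met.id, f"duplicate metabolite id {met.id!r}"))
        seen_mets.add(met.id)
        if not met.compartment:
            issues.append(ValidationIssue("error", met.id, f"metabolite {met.id!r} has empty compartment"))

    seen_rxns: set[str] = set()
    for rxn in model.reactions:
        if not rxn.id:
            issues.append(ValidationIssue("error", "", "reaction with empty id"))
            continue
        if rxn.id in seen_rxns:
            issues.append(ValidationIssue("error", rxn.id, f"duplicate reaction id {rxn.id!r}"))
        seen_rxns.add(rxn.id)
        if rxn.lower_bound > rxn.upper_bound:
            issues.append(
                ValidationIssue(
                    "error",
                    rxn.id,
                    f"reaction {rxn.id!r} has inverted bounds: "
                    f"lower_bound {rxn.lower_bound} > upper_bound {rxn.upper_bound}",
                )
            )
        if not rxn.stoichiometry:
            issues.append(
                ValidationIssue("error", rxn.id, f"reaction {rxn.id!r} has empty stoichiometry")
            )
        for met_id in rxn.stoichiometry:
            if met_id not in seen_mets and not model.has_metabolite(met_id):
                issues.append(
                    ValidationIssue(
                        "error",
                        rxn.id,
                        f"reaction {rxn.id!r} references unknown metabolite {met_id!r}",
                    )
                )
        if rxn.gene_association:
            try:
                normalize_gpr(rxn.gene_association)
            except GPRParseError as exc:
                issues.append(
                    ValidationIssue(
                        "warning", rxn.id, f"reaction {rxn.id!r} has unparseable gene association: {exc}"
                    )
                )

    if not model.objective_reaction_id:
        issues.append(ValidationIssue("error", "", "model has no objective reaction"))
    elif model.objective_reaction_id not in seen_rxns:
        issues.append(
            ValidationIssue(
                "error",
                model.objective_reaction_id,
                f"objective reaction {model.objective_reaction_id!r} does not exist",
            )
        )
    return ValidationReport(issues)


# ---------------------------------------------------------------------------
# TAG augmentation
# ---------------------------------------------------------------------------


def augment_tag_synthesis(
    model: StoichiometricModel,
    dag_id: str,
    acyl_coa_ids: list[str],
    tag_id: str,
    coa_id: str,
    add_demand: bool = True,
) -> tuple[StoichiometricModel, ModelDelta]:
    """Add acyl-CoA–dependent TAG esterification to a model.

    For each acyl-CoA species ``a``, adds the irreversible DGAT-style
    reaction ``DGAT_<a>: 1 DAG + 1 a → 1 TAG + 1 CoA`` with bounds
    ``[0, default_bound]``.  If *add_demand* is true and no boundary
    reaction already consumes TAG, a demand ``DM_tag: 1 TAG → ∅`` is added
    so the storage lipid can be drained.  The TAG metabolite is created if
    it does not yet exist.  The biomass equation is left bit-identical.

    Returns the augmented model (a new object) and a :class:`ModelDelta`
    recording exactly the additions; :func:`revert_delta` restores the
    input model exactly.
    """
    for species, role in [(dag_id, "DAG"), (coa_id, "CoA")] + [(a, "acyl-CoA") for a in acyl_coa_ids]:
        if not model.has_metabolite(species):
            raise ModelError(f"{role} species {species!r} not found in model {model.id!r}")
    if not acyl_coa_ids:
        raise ModelError("at least one acyl-CoA species id is required")
    for acyl in acyl_coa_ids:
        roles = [dag_id, acyl, tag_id, coa_id]
        if len(set(roles)) != 4:
            raise ModelError(
                f"DAG/acyl-CoA/TAG/CoA species must be distinct, got {roles}"
            )

    new_model = model.copy()
    delta = ModelDelta(note="acyl-CoA-dependent TAG synthesis augmentation")

    if not new_model.has_metabolite(tag_id):
        tag_met = Metabolite(id=tag_id, name="triacylglycerol", compartment=model.get_metabolite(dag_id).compartment)
        new_model.metabolites.append(tag_met)
        delta.added_metabolites.append(tag_met.copy())

    for acyl in acyl_coa_ids:
        rxn_id = f"DGAT_{acyl}"
        if new_model.has_reaction(rxn_id):
            raise ModelError(f"reaction id {rxn_id!r} already exists in model {model.id!r}")
        rxn = Reaction(
            id=rxn_id,
            name=f"diacylglycerol acyltransferase ({acyl})",
            stoichiometry={dag_id: -1.0, acyl: -1.0, tag_id: 1.0, coa_id: 1.0},
            lower_bound=0.0,
            upper_bound=new_model.default_bound,
            subsystem="Triacylglycerol biosynthesis",
        )
        new_model.reactions.append(rxn)
        delta.added_reactions.append(rxn.copy())

    if add_demand:
        has_tag_sink = any(
            r.is_boundary and r.stoichiometry.get(tag_id, 0.0) < 0 for r in model.reactions
        )
        if not has_tag_sink:
            dm_id = "DM_tag"
            if new_model.has_reaction(dm_id):
                raise ModelError(f"reaction id {dm_id!r} already exists in model {model.id!r}")
            dm = Reaction(
                id=dm_id,
                name="TAG demand",
                stoichiometry={tag_id: -1.0},
                lower_bound=0.0,
                upper_bound=new_model.default_bound,
                subsystem="Triacylglycerol biosynthesis",
            )
            new_model.reactions.append(dm)
            delta.added_reactions.append(dm.copy())

    return new_model, delta


def revert_delta(model: StoichiometricModel, delta: ModelDelta) -> StoichiometricModel:
    """Undo a :class:`ModelDelta`, restoring the pre-edit model exactly."""
    reverted = model.copy()
    added_rxn_ids = {r.id for r in delta.added_reactions}
    added_met_ids = {m.id for m in delta.added_metabolites}
    reverted.reactions = [r for r in reverted.reactions if r.id not in added_rxn_ids]
    reverted.metabolites = [m for m in reverted.metabolites if m.id not in added_met_ids]
    for rxn_id, (old_lb, old_ub, _new_lb, _new_ub) in delta.modified_bounds.items():
        rxn = reverted.get_reaction(rxn_id)
        rxn.lower_bound, rxn.upper_bound = old_lb, old_ub
    return reverted


# ---------------------------------------------------------------------------
# knockouts and GPR
# ---------------------------------------------------------------------------


def apply_knockouts(model: StoichiometricModel, reaction_ids) -> StoichiometricModel:
    """Return a new model where each named reaction has bounds fixed to zero."""
    reaction_ids = set(reaction_ids)
    for rid in reaction_ids:
        model.get_reaction(rid)  # raises ModelError on unknown id
    knocked = model.copy()
    for rxn in knocked.reactions:
        if rxn.id in reaction_ids:
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return knocked


def evaluate_gpr(association: str | None, deleted_genes) -> bool:
    """Reaction still catalyzable after the gene deletions (see :mod:`tagknock.gpr`)."""
    return _evaluate_gpr(association, deleted_genes)


def reactions_disabled_by_genes(model: StoichiometricModel, deleted_genes) -> set[str]:
    """Gene-level knockout mode: reactions whose GPR evaluates false."""
    deleted = set(deleted_genes)
    return {
        r.id
        for r in model.reactions
        if r.gene_association and not _evaluate_gpr(r.gene_association, deleted)
    }


def genes_for_candidate(model: StoichiometricModel, reaction_ids) -> dict[str, list[str]]:
    """Per-reaction gene lists (first-occurrence order, deduplicated)."""
    out: dict[str, list[str]] = {}
    for rid in sorted(set(reaction_ids)):
        rxn = model.get_reaction(rid)
        out[rid] = gpr_genes(rxn.gene_association)
    return out
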