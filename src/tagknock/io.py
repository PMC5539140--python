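"""Model readers/writers: SBML Level 3 (FBC flux bounds + gene products)
and a one-to-one JSON schema (``json-v1``), plus tabular output writers.

json-v1 schema
--------------
A single JSON object::

    {
      "id": str,
      "default_bound": float,
      "objective_reaction_id": str,
      "metabolites": [{"id", "name", "compartment", "formula", "charge"}],
      "reactions": [{"id", "name", "stoichiometry": {met_id: coeff},
                     "lower_bound", "upper_bound", "gene_association",
                     "objective_coefficient", "subsystem"}]
    }

A reaction may omit both bounds and instead carry ``"reversible": bool``;
the loader then defaults to ``[-default_bound, default_bound]`` when
reversible and ``[0, default_bound]`` otherwise, recording a warning.
Output ordering follows model order, so identical models serialize to
byte-identical files.

The SBML dialect targets Level 3 Version 1 with FBC v2: flux bounds as
constant parameters, the objective as an fbc maximization objective, and
gene associations as fbc gene-product associations.  COBRA-style ``M_``,
``R_`` and ``G_`` SId prefixes are added on write and stripped on read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import libsbml

from . import gpr as _gpr
from .core import Metabolite, ModelError, Reaction, StoichiometricModel, genes_for_candidate

__all__ = [
    "ModelDocument",
    "ModelIOError",
    "read_model",
    "write_model",
    "write_candidate_table",
    "write_flux_table",
]

DIALECTS = ("json-v1", "sbml3-fbc")


class ModelIOError(ValueError):
    pass


@dataclass
class ModelDocument:
    model: StoichiometricModel
    source_path: str = ""
    dialect: str = "json-v1"
    warnings: list[str] = field(default_factory=list)


def _sniff_dialect(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".xml", ".sbml"):
        return "sbml3-fbc"
    if suffix == ".json":
        return "json-v1"
    # content sniff
    head = path.read_text(errors="replace")[:200].lstrip()
    if head.startswith("<"):
        return "sbml3-fbc"
    if head.startswith("{"):
        return "json-v1"
    raise ModelIOError(f"cannot determine model dialect of {path}")


def read_model(path, dialect: str | None = None) -> ModelDocument:
    """Read a model file; dialect is auto-detected from suffix/content."""
    path = Path(path)
    if not path.exists():
        raise ModelIOError(f"model file not found: {path}")
    dialect = dialect or _sniff_dialect(path)
    if dialect == "json-v1":
        model, warnings = _read_json(path)
    elif dialect == "sbml3-fbc":
        model, warnings = _read_sbml(path)
    else:
        raise ModelIOError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if not model.objective_reaction_id:
        raise ModelIOError(f"model in {path} declares no objective reaction")
    return ModelDocument(model=model, source_path=str(path), dialect=dialect, warnings=warnings)


def write_model(doc_or_model, path, dialect: str | None = None) -> None:
    """Write a model; ``read_model(write_model(m)) == m`` for both dialects."""
    if isinstance(doc_or_model, ModelDocument):
        model = doc_or_model.model
        dialect = dialect or doc_or_model.dialect
    else:
        model = doc_or_model
    path = Path(path)
    dialect = dialect or _sniff_dialect_for_write(path)
    if dialect == "json-v1":
        _write_json(model, path)
    elif dialect == "sbml3-fbc":
        _write_sbml(model, path)
    else:
        raise ModelIOError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def _sniff_dialect_for_write(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".xml", ".sbml"):
        return "sbml3-fbc"
    return "json-v1"


# ---------------------------------------------------------------------------
# json-v1
# ---------------------------------------------------------------------------


def model_to_dict(model: StoichiometricModel) -> dict:
    return {
        "id": model.id,
        "default_bound": model.default_bound,
        "objective_reaction_id": model.objective_reaction_id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": m.formula,
                "charge": m.charge,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_association": r.gene_association,
                "objective_coefficient": r.objective_coefficient,
                "subsystem": r.subsystem,
            }
            for r in model.reactions
        ],
    }


def model_from_dict(data: dict) -> tuple[StoichiometricModel, list[str]]:
    warnings: list[str] = []
    default_bound = float(data.get("default_bound", 1000.0))
    metabolites = [
        Metabolite(
            id=m["id"],
            name=m.get("name", ""),
            compartment=m.get("compartment", "c"),
            formula=m.get("formula"),
            charge=m.get("charge"),
        )
        for m in data.get("metabolites", [])
    ]
    reactions = []
    for r in data.get("reactions", []):
        lb, ub = r.get("lower_bound"), r.get("upper_bound")
        if lb is None or ub is None:
            reversible = bool(r.get("reversible", False))
            if lb is None:
                lb = -default_bound if reversible else 0.0
            if ub is None:
                ub = default_bound
            warnings.append(
                f"reaction {r['id']!r} missing bounds; defaulted to [{lb}, {ub}]"
            )
        gene_association = r.get("gene_association")
        if gene_association:
            try:
                _gpr.parse_gpr(gene_association)
            except _gpr.GPRParseError as exc:
                warnings.append(
                    f"reaction {r['id']!r}: unparseable gene association dropped ({exc})"
                )
                gene_association = None
        reactions.append(
            Reaction(
                id=r["id"],
                name=r.get("name", ""),
                stoichiometry={k: float(v) for k, v in r.get("stoichiometry", {}).items()},
                lower_bound=float(lb),
                upper_bound=float(ub),
                gene_association=gene_association,
                objective_coefficient=float(r.get("objective_coefficient", 0.0)),
                subsystem=r.get("subsystem"),
            )
        )
    model = StoichiometricModel(
        id=data.get("id", "model"),
        metabolites=metabolites,
        reactions=reactions,
        objective_reaction_id=data.get("objective_reaction_id", ""),
        default_bound=default_bound,
    )
    return model, warnings


def _read_json(path: Path) -> tuple[StoichiometricModel, list[str]]:
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelIOError(f"{path} is not valid JSON: {exc}") from exc
    return model_from_dict(data)


def _write_json(model: StoichiometricModel, path: Path) -> None:
    text = json.dumps(model_to_dict(model), indent=1, ensure_ascii=True)
    path.write_text(text + "\n")


# ---------------------------------------------------------------------------
# sbml3-fbc
# ---------------------------------------------------------------------------

_DEFAULT_BOUND_PARAM = "tk_default_bound"


def _sid(prefix: str, raw: str) -> str:
    safe = "".join(ch if (ch.isalnum() or ch == "_") else "_" for ch in raw)
    return f"{prefix}{safe}"


def _strip(prefix: str, sid: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def _gpr_to_fbc(node, assoc_parent, gene_sids: dict[str, str]):
    kind = node[0]
    if kind == "gene":
        ref = assoc_parent.createGeneProductRef()
        ref.setGeneProduct(gene_sids[node[1]])
        return
    group = assoc_parent.createAnd() if kind == "and" else assoc_parent.createOr()
    for child in node[1]:
        _gpr_to_fbc(child, group, gene_sids)


def _fbc_to_gpr(assoc, labels: dict[str, str]):
    if assoc is None:
        return None
    code = assoc.getTypeCode()
    if code == libsbml.SBML_FBC_GENEPRODUCTREF:
        return ("gene", labels.get(assoc.getGeneProduct(), _strip("G_", assoc.getGeneProduct())))
    children = [
        _fbc_to_gpr(assoc.getAssociation(i), labels) for i in range(assoc.getNumAssociations())
    ]
    if code == libsbml.SBML_FBC_AND:
        return ("and", children)
    if code == libsbml.SBML_FBC_OR:
        return ("or", children)
    raise ModelIOError(f"unsupported gene association node type {code}")


def _write_sbml(model: StoichiometricModel, path: Path) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(_sid("", model.id) or "model")
    sbml_model.setName(model.id)
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    compartments = []
    for met in model.metabolites:
        if met.compartment not in compartments:
            compartments.append(met.compartment)
    for comp_id in compartments:
        comp = sbml_model.createCompartment()
        comp.setId(_sid("", comp_id))
        comp.setConstant(True)
        comp.setSize(1.0)

    for met in model.metabolites:
        sp = sbml_model.createSpecies()
        sp.setId(_sid("M_", met.id))
        sp.setName(met.name)
        sp.setCompartment(_sid("", met.compartment))
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        splug = sp.getPlugin("fbc")
        if met.formula is not None:
            splug.setChemicalFormula(met.formula)
        if met.charge is not None:
            splug.setCharge(int(met.charge))

    # shared flux-bound parameters; one pair per reaction keeps round-trips exact
    def make_param(pid: str, value: float):
        par = sbml_model.createParameter()
        par.setId(pid)
        par.setValue(value)
        par.setConstant(True)

    make_param(_DEFAULT_BOUND_PARAM, model.default_bound)

    gene_sids: dict[str, str] = {}
    for rxn in model.reactions:
        for gene in _gpr.gpr_genes(rxn.gene_association):
            if gene not in gene_sids:
                gene_sids[gene] = _sid("G_", gene)
    for gene, sid in gene_sids.items():
        gp = mplug.createGeneProduct()
        gp.setId(sid)
        gp.setLabel(gene)

    objective = mplug.createObjective()
    objective.setId("obj")
    objective.setType("maximize")
    mplug.setActiveObjectiveId("obj")

    for rxn in model.reactions:
        rid = _sid("R_", rxn.id)
        sr = sbml_model.createReaction()
        sr.setId(rid)
        sr.setName(rxn.name)
        sr.setReversible(rxn.lower_bound < 0)
        sr.setFast(False)
        for met_id, coeff in rxn.stoichiometry.items():
            if coeff < 0:
                ref = sr.createReactant()
                ref.setStoichiometry(-coeff)
            else:
                ref = sr.createProduct()
                ref.setStoichiometry(coeff)
            ref.setSpecies(_sid("M_", met_id))
            ref.setConstant(True)
        rplug = sr.getPlugin("fbc")
        lb_id, ub_id = f"{rid}_lb", f"{rid}_ub"
        make_param(lb_id, rxn.lower_bound)
        make_param(ub_id, rxn.upper_bound)
        rplug.setLowerFluxBound(lb_id)
        rplug.setUpperFluxBound(ub_id)
        if rxn.gene_association:
            node = _gpr.parse_gpr(rxn.gene_association)
            assoc = rplug.createGeneProductAssociation()
            if node[0] == "gene":
                ref = assoc.createGeneProductRef()
                ref.setGeneProduct(gene_sids[node[1]])
            else:
                _gpr_to_fbc(node, assoc, gene_sids)
        if rxn.objective_coefficient:
            fo = objective.createFluxObjective()
            fo.setReaction(rid)
            fo.setCoefficient(rxn.objective_coefficient)
        if rxn.subsystem:
            sr.setNotes(
                f'<body xmlns="http://www.w3.org/1999/xhtml">'
                f"<p>subsystem: {rxn.subsystem}</p></body>"
            )

    # record which reaction is the designated objective even if several carry
    # objective coefficients
    sbml_model.setMetaId("meta_" + (_sid("", model.id) or "model"))
    objective.setName(_sid("R_", model.objective_reaction_id))

    writer = libsbml.SBMLWriter()
    if not writer.writeSBMLToFile(doc, str(path)):
        raise ModelIOError(f"failed to write SBML to {path}")


def _read_sbml(path: Path) -> tuple[StoichiometricModel, list[str]]:
    warnings: list[str] = []
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msgs = [
            doc.getError(i).getMessage()
            for i in range(doc.getNumErrors())
            if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        ]
        raise ModelIOError(f"SBML parse errors in {path}: " + "; ".join(msgs[:3]))
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelIOError(f"{path} contains no SBML model")
    mplug = sbml_model.getPlugin("fbc")

    params = {
        sbml_model.getParameter(i).getId(): sbml_model.getParameter(i).getValue()
        for i in range(sbml_model.getNumParameters())
    }
    default_bound = params.get(_DEFAULT_BOUND_PARAM, 1000.0)

    metabolites = []
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        splug = sp.getPlugin("fbc")
        formula = None
        charge = None
        if splug is not None:
            if splug.isSetChemicalFormula():
                formula = splug.getChemicalFormula()
            if splug.isSetCharge():
                charge = splug.getCharge()
        metabolites.append(
            Metabolite(
                id=_strip("M_", sp.getId()),
                name=sp.getName(),
                compartment=sp.getCompartment(),
                formula=formula,
                charge=charge,
            )
        )

    labels: dict[str, str] = {}
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            labels[gp.getId()] = gp.getLabel() or _strip("G_", gp.getId())

    objective_coeffs: dict[str, float] = {}
    objective_rid = ""
    if mplug is not None and mplug.getNumObjectives() > 0:
        obj = mplug.getObjective(mplug.getActiveObjectiveId()) or mplug.getObjective(0)
        for i in range(obj.getNumFluxObjectives()):
            fo = obj.getFluxObjective(i)
            objective_coeffs[fo.getReaction()] = fo.getCoefficient()
        if obj.isSetName():
            objective_rid = _strip("R_", obj.getName())

    reactions = []
    for i in range(sbml_model.getNumReactions()):
        sr = sbml_model.getReaction(i)
        rplug = sr.getPlugin("fbc")
        stoich: dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            met = _strip("M_", ref.getSpecies())
            stoich[met] = stoich.get(met, 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            met = _strip("M_", ref.getSpecies())
            stoich[met] = stoich.get(met, 0.0) + ref.getStoichiometry()

        lb = ub = None
        if rplug is not None:
            if rplug.isSetLowerFluxBound():
                lb = params.get(rplug.getLowerFluxBound())
            if rplug.isSetUpperFluxBound():
                ub = params.get(rplug.getUpperFluxBound())
        if lb is None or ub is None:
            reversible = sr.getReversible()
            lb = (-default_bound if reversible else 0.0) if lb is None else lb
            ub = default_bound if ub is None else ub
            warnings.append(
                f"reaction {sr.getId()!r} missing flux bounds; defaulted to [{lb}, {ub}]"
            )

        gene_association = None
        if rplug is not None and rplug.isSetGeneProductAssociation():
            try:
                node = _fbc_to_gpr(rplug.getGeneProductAssociation().getAssociation(), labels)
                gene_association = _gpr.gpr_to_string(node) or None
            except ModelIOError as exc:
                warnings.append(f"reaction {sr.getId()!r}: gene association dropped ({exc})")

        subsystem = None
        if sr.isSetNotes():
            notes = sr.getNotesString()
            marker = "subsystem: "
            if marker in notes:
                subsystem = notes.split(marker, 1)[1].split("<", 1)[0].strip()

        reactions.append(
            Reaction(
                id=_strip("R_", sr.getId()),
                name=sr.getName(),
                stoichiometry=stoich,
                lower_bound=float(lb),
                upper_bound=float(ub),
                gene_association=gene_association,
                objective_coefficient=float(objective_coeffs.get(sr.getId(), 0.0)),
                subsystem=subsystem,
            )
        )

    if not objective_rid:
        # fall back to the first reaction carrying an objective coefficient
        for r in reactions:
            if r.objective_coefficient:
                objective_rid = r.id
                break

    model = StoichiometricModel(
        id=sbml_model.getName() or sbml_model.getId(),
        metabolites=metabolites,
        reactions=reactions,
        objective_reaction_id=objective_rid,
        default_bound=float(default_bound),
    )
    return model, warnings


# ---------------------------------------------------------------------------
# tabular writers
# ---------------------------------------------------------------------------


def write_candidate_table(candidates, model: StoichiometricModel, path) -> None:
    """Write the ranked knockout-candidate table as TSV.

    Columns: rank, reaction_ids (comma-joined sorted), outer_objective,
    inner_objective, genes (semicolon-joined across the candidate's
    reactions), subsystem.  Mirrors the layout of a published
    reaction/enzyme/putative-genes candidate listing.
    """
    lines = ["rank\treaction_ids\touter_objective\tinner_objective\tgenes\tsubsystem"]
    for rank, cand in enumerate(candidates, start=1):
        rids = sorted(cand.deleted_reaction_ids)
        gene_map = cand.genes or genes_for_candidate(model, cand.deleted_reaction_ids)
        genes = [g for rid in rids for g in gene_map.get(rid, [])]
        seen: dict[str, None] = {}
        for g in genes:
            seen.setdefault(g)
        subsystems = []
        for rid in rids:
            sub = model.get_reaction(rid).subsystem
            if sub and sub not in subsystems:
                subsystems.append(sub)
        lines.append(
            "\t".join(
                [
                    str(rank),
                    ",".join(rids),
                    f"{cand.outer_objective:.6f}",
                    f"{cand.inner_objective:.6f}",
                    ";".join(seen),
                    ";".join(subsystems),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_flux_table(solution, path) -> None:
    """TSV flux table (reaction_id, flux) with 6-decimal formatting."""
    lines = ["reaction_id\tflux"]
    for rid, flux in solution.fluxes.items():
        lines.append(f"{rid}\t{flux:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")
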