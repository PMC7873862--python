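"""Readers and writers for constraint-based models.

Two dialects are supported:

* ``json`` — a BiGG-style JSON document with top-level ``metabolites``,
  ``reactions``, ``genes``, ``compartments`` and ``objective`` lists; GPR
  rules are stored as infix strings under ``gene_reaction_rule``.
* ``sbml`` — SBML Level 3 with the FBC version 2 package: flux bounds as
  parameters, GPR rules as ``fbc:geneProductAssociation``, the objective as
  an ``fbc:objective``.

Reading a written file reproduces the model at id-level content (ids,
stoichiometry, bounds, GPR strings, objective, compartment suffixes).
"""

from __future__ import annotations

import json
from typing import Dict, Optional

import libsbml

from .core import (
    FormulaError,
    Gene,
    GprExpr,
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
    ReactionKind,
    format_formula,
    parse_formula,
    parse_gpr,
)

__all__ = ["read_model", "write_model", "model_to_dict", "model_from_dict"]

# SBO terms used to round-trip the reaction kind through SBML (the terms the
# COBRA community uses for boundary pseudo-reactions).
_KIND_TO_SBO = {
    ReactionKind.EXCHANGE: "SBO:0000627",
    ReactionKind.DEMAND: "SBO:0000628",
    ReactionKind.SINK: "SBO:0000632",
    ReactionKind.BIOMASS: "SBO:0000629",
    ReactionKind.TRANSPORT: "SBO:0000655",
    ReactionKind.METABOLIC: "SBO:0000176",
}
_SBO_TO_KIND = {v: k for k, v in _KIND_TO_SBO.items()}


def infer_kind(rxn_id: str, stoichiometry: Dict[str, float]) -> ReactionKind:
    """Guess a reaction kind from id conventions when none is recorded."""
    rid = rxn_id.upper()
    base = rid[3:] if rid.startswith("RT_") else rid
    if base.startswith("EX_"):
        return ReactionKind.EXCHANGE
    if base.startswith("DM_"):
        return ReactionKind.DEMAND
    if base.startswith("SK_") or base.startswith("SINK_"):
        return ReactionKind.SINK
    if "BIOMASS" in rid:
        return ReactionKind.BIOMASS
    if len(stoichiometry) <= 1:
        return ReactionKind.EXCHANGE
    return ReactionKind.METABOLIC


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------


def model_to_dict(model: MetabolicModel) -> dict:
    doc = {
        "id": model.id,
        "compartments": dict(model.compartments),
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "formula": format_formula(m.formula) if m.formula is not None else None,
                "charge": m.charge,
                "compartment": m.compartment,
            }
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": r.gpr.to_string(),
                "subsystem": r.subsystem,
                "kind": r.kind.value,
            }
            for r in model.reactions.values()
        ],
        "genes": [{"id": g.id, "name": g.name} for g in model.genes.values()],
    }
    if model.objective is not None:
        doc["objective"] = {"reaction": model.objective[0], "direction": model.objective[1]}
    return doc


def model_from_dict(doc: dict) -> MetabolicModel:
    model = MetabolicModel(id=doc.get("id", "model"))
    comps = doc.get("compartments", {})
    if isinstance(comps, list):  # tolerate [{"id":..,"name":..}] form
        comps = {c["id"]: c.get("name", "") for c in comps}
    model.compartments = dict(comps)
    for i, m in enumerate(doc.get("metabolites", [])):
        if "id" not in m:
            raise ModelError(f"metabolite record #{i} lacks an id: {m!r}")
        formula = m.get("formula")
        try:
            parsed = parse_formula(formula) if formula not in (None, "") else None
        except FormulaError as exc:
            raise ModelError(f"metabolite {m['id']!r}: {exc}") from exc
        comp = m.get("compartment", "")
        if comp and comp not in model.compartments:
            raise ModelError(f"metabolite {m['id']!r}: unknown compartment {comp!r}")
        model.add_metabolite(
            Metabolite(id=m["id"], name=m.get("name", ""), formula=parsed,
                       charge=m.get("charge"), compartment=comp)
        )
    for g in doc.get("genes", []):
        model.genes[g["id"]] = Gene(g["id"], g.get("name", ""))
    objective = None
    for i, r in enumerate(doc.get("reactions", [])):
        if "id" not in r:
            raise ModelError(f"reaction record #{i} lacks an id: {r!r}")
        stoich = {k: float(v) for k, v in r.get("metabolites", {}).items()}
        kind = r.get("kind")
        rxn = Reaction(
            id=r["id"],
            stoichiometry=stoich,
            lower_bound=float(r.get("lower_bound", 0.0)),
            upper_bound=float(r.get("upper_bound", 1000.0)),
            gpr=parse_gpr(r.get("gene_reaction_rule", "")),
            name=r.get("name", ""),
            subsystem=r.get("subsystem", ""),
            kind=ReactionKind(kind) if kind else infer_kind(r["id"], stoich),
        )
        model.add_reaction(rxn)
        if objective is None and r.get("objective_coefficient"):
            objective = (rxn.id, "max")  # BiGG-style objective marking
    if "objective" in doc:
        objective = (doc["objective"]["reaction"], doc["objective"].get("direction", "max"))
    model.objective = objective
    model.validate()
    return model


# ---------------------------------------------------------------------------
# SBML Level 3 + FBC v2
# ---------------------------------------------------------------------------

def _sid(prefix: str, raw: str) -> str:
    """SBML SId: prefix and replace characters outside [A-Za-z0-9_]."""
    safe = "".join(ch if ch.isalnum() or ch == "_" else "__" for ch in raw)
    return prefix + safe


def _gpr_to_association(gpr: GprExpr, parent) -> None:
    if gpr.op == "leaf":
        ref = parent.createGeneProductRef()
        ref.setGeneProduct(_sid("G_", gpr.gene))
        return
    node = parent.createAnd() if gpr.op == "and" else parent.createOr()
    for child in gpr.children:
        _gpr_to_association(child, node)


def _association_to_gpr(assoc) -> GprExpr:
    if assoc is None:
        return GprExpr.empty()
    if isinstance(assoc, libsbml.GeneProductRef):
        return GprExpr.leaf(assoc.getGeneProduct()[2:])  # strip "G_"
    children = [
        _association_to_gpr(assoc.getAssociation(i))
        for i in range(assoc.getNumAssociations())
    ]
    if isinstance(assoc, libsbml.FbcAnd):
        return GprExpr.all_of(children)
    if isinstance(assoc, libsbml.FbcOr):
        return GprExpr.any_of(children)
    raise ModelError(f"unsupported gene association node {type(assoc).__name__}")


def _write_sbml(model: MetabolicModel, path: str) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(_sid("", model.id) or "model")
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    for token, name in model.compartments.items():
        comp = sbml_model.createCompartment()
        comp.setId(_sid("", token))
        comp.setName(name or token)
        comp.setConstant(True)
        comp.setSize(1.0)

    for met in model.metabolites.values():
        sp = sbml_model.createSpecies()
        sp.setId(_sid("M_", met.id))
        sp.setName(met.name or met.id)
        sp.setCompartment(_sid("", met.compartment or next(iter(model.compartments), "c")))
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        sp.setInitialConcentration(0.0)
        splug = sp.getPlugin("fbc")
        if met.charge is not None:
            splug.setCharge(int(met.charge))
        if met.formula is not None:
            splug.setChemicalFormula(format_formula(met.formula))

    for gene in model.genes.values():
        gp = mplug.createGeneProduct()
        gp.setId(_sid("G_", gene.id))
        gp.setLabel(gene.id)
        if gene.name:
            gp.setName(gene.name)

    bound_params: Dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            par = sbml_model.createParameter()
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions.values():
        sr = sbml_model.createReaction()
        sr.setId(_sid("R_", rxn.id))
        sr.setName(rxn.name or rxn.id)
        sr.setReversible(rxn.lower_bound < 0)
        sr.setFast(False)
        sr.setSBOTerm(_KIND_TO_SBO[rxn.kind])
        for met_id, coef in rxn.stoichiometry.items():
            ref = sr.createReactant() if coef < 0 else sr.createProduct()
            ref.setSpecies(_sid("M_", met_id))
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound))
        if not rxn.gpr.is_empty:
            gpa = rplug.createGeneProductAssociation()
            _gpr_to_association(rxn.gpr, gpa)

    if model.objective is not None:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize" if model.objective[1] == "max" else "minimize")
        fo = obj.createFluxObjective()
        fo.setReaction(_sid("R_", model.objective[0]))
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"failed to write SBML to {path}")


def _strip(prefix: str, sid: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def _read_sbml(path: str) -> MetabolicModel:
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelError(f"SBML parse error: {err.getMessage() if err else 'unknown'}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelError(f"no model element in {path}")
    mplug = sbml_model.getPlugin("fbc")

    model = MetabolicModel(id=sbml_model.getId() or "model")
    for i in range(sbml_model.getNumCompartments()):
        comp = sbml_model.getCompartment(i)
        model.compartments[comp.getId()] = comp.getName() or comp.getId()

    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        splug = sp.getPlugin("fbc")
        formula = None
        charge = None
        if splug is not None:
            if splug.isSetChemicalFormula():
                formula = parse_formula(splug.getChemicalFormula())
            if splug.isSetCharge():
                charge = splug.getCharge()
        model.add_metabolite(
            Metabolite(id=_strip("M_", sp.getId()), name=sp.getName(),
                       formula=formula, charge=charge,
                       compartment=sp.getCompartment())
        )

    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            gid = gp.getLabel() or _strip("G_", gp.getId())
            model.genes[gid] = Gene(gid, gp.getName() or "")

    for i in range(sbml_model.getNumReactions()):
        sr = sbml_model.getReaction(i)
        stoich: Dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            met = _strip("M_", ref.getSpecies())
            stoich[met] = stoich.get(met, 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            met = _strip("M_", ref.getSpecies())
            stoich[met] = stoich.get(met, 0.0) + ref.getStoichiometry()
        stoich = {k: v for k, v in stoich.items() if v != 0}
        rplug = sr.getPlugin("fbc")
        lb, ub = 0.0, 1000.0
        gpr = GprExpr.empty()
        if rplug is not None:
            lbp = sbml_model.getParameter(rplug.getLowerFluxBound())
            ubp = sbml_model.getParameter(rplug.getUpperFluxBound())
            if lbp is not None:
                lb = lbp.getValue()
            if ubp is not None:
                ub = ubp.getValue()
            gpa = rplug.getGeneProductAssociation()
            if gpa is not None:
                gpr = _association_to_gpr(gpa.getAssociation())
                # SBML gene product refs point at SIds; map back to labels
                label_map = {
                    _sid("G_", g): g for g in model.genes
                }

                def relabel(expr: GprExpr) -> GprExpr:
                    if expr.op == "leaf":
                        sid = "G_" + expr.gene
                        return GprExpr.leaf(label_map.get(sid, expr.gene))
                    if expr.op in ("and", "or"):
                        return GprExpr(expr.op, children=tuple(relabel(c) for c in expr.children))
                    return expr

                gpr = relabel(gpr)
        rid = _strip("R_", sr.getId())
        kind = _SBO_TO_KIND.get(sr.getSBOTermID(), None) or infer_kind(rid, stoich)
        model.add_reaction(
            Reaction(id=rid, stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
                     gpr=gpr, name=sr.getName(), kind=kind)
        )

    if mplug is not None and mplug.getNumObjectives() > 0:
        obj = mplug.getObjective(mplug.getActiveObjectiveId()) or mplug.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            fo = obj.getFluxObjective(0)
            direction = "max" if obj.getType() == "maximize" else "min"
            model.objective = (_strip("R_", fo.getReaction()), direction)

    model.validate()
    return model


# ---------------------------------------------------------------------------
# Public entry points
# ---------------------------------------------------------------------------


def _dialect_from_path(path: str, dialect: Optional[str]) -> str:
    if dialect is not None:
        return dialect
    p = str(path).lower()
    if p.endswith(".json"):
        return "json"
    if p.endswith((".xml", ".sbml")):
        return "sbml"
    raise ValueError(f"cannot infer dialect from path {path!r}; pass dialect=")


def read_model(path: str, dialect: Optional[str] = None) -> MetabolicModel:
    """Load a model from ``json`` or ``sbml`` (inferred from the extension)."""
    dialect = _dialect_from_path(path, dialect)
    if dialect == "json":
        with open(path) as fh:
            return model_from_dict(json.load(fh))
    if dialect == "sbml":
        return _read_sbml(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_model(model: MetabolicModel, path: str, dialect: Optional[str] = None) -> None:
    """Write a model as ``json`` or ``sbml`` (inferred from the extension)."""
    dialect = _dialect_from_path(path, dialect)
    if dialect == "json":
        with open(path, "w") as fh:
            json.dump(model_to_dict(model), fh, indent=1, sort_keys=False)
            fh.write("\n")
    elif dialect == "sbml":
        _write_sbml(model, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
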