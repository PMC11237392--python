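"""SBML Level 3 + fbc v2 reader/writer.

Only the constraint-based subset is covered: species, reactions with
flux bounds, fbc gene products with Boolean gene-product associations,
and the active fbc objective.  Other SBML levels are rejected with a
clear message rather than half-read.
"""

from __future__ import annotations

import libsbml

from .gpr import AND, OR, GPRNode, format_gpr, genes_of
from .model import (
    DEFAULT_UPPER_BOUND,
    Gene,
    Metabolite,
    Model,
    ModelValidationError,
    Reaction,
    format_formula,
    infer_origin,
    parse_formula,
)

__all__ = ["read_sbml", "write_sbml", "SBMLReadError"]


class SBMLReadError(ValueError):
    """Malformed or unsupported SBML input."""


def _association_to_gpr(assoc: libsbml.FbcAssociation) -> GPRNode:
    if assoc.isGeneProductRef():
        return GPRNode("leaf", gene_id=assoc.getGeneProduct())
    if assoc.isFbcAnd():
        kind = AND
    elif assoc.isFbcOr():
        kind = OR
    else:  # pragma: no cover - defensive
        raise SBMLReadError(f"unsupported association element {assoc.getElementName()}")
    children = tuple(
        _association_to_gpr(assoc.getAssociation(i))
        for i in range(assoc.getNumAssociations())
    )
    if len(children) == 1:
        return children[0]
    return GPRNode(kind, children=children)


def _link_allele_partners(model: Model) -> None:
    """Re-link _Scer/_Seub allele pairs sharing a common base name."""
    by_base: dict[str, dict[str, str]] = {}
    for gene in model.genes.values():
        for suffix in ("_Scer", "_Seub"):
            if gene.id.endswith(suffix):
                base = gene.id[: -len(suffix)]
                by_base.setdefault(base, {})[suffix] = gene.id
    for pair in by_base.values():
        if len(pair) == 2:
            a, b = pair["_Scer"], pair["_Seub"]
            model.genes[a].allele_partner = b
            model.genes[b].allele_partner = a


def read_sbml(path: str) -> Model:
    """Read an SBML L3 + fbc model from ``path``.

    Gene origins are inferred from allele suffixes (``_Scer``/``_Seub``/
    ``_Spast``) and redundant allele pairs are re-linked.  Raises
    :class:`SBMLReadError` on parse errors (naming the element) or when
    a GPR references an undeclared gene product.
    """
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise SBMLReadError(
            f"SBML parse error: {err.getMessage().strip()} "
            f"(line {err.getLine()})"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise SBMLReadError("document contains no <model> element")
    if doc.getLevel() != 3:
        raise SBMLReadError(
            f"only SBML Level 3 is supported, got Level {doc.getLevel()}"
        )
    mplug = sbml_model.getPlugin("fbc")
    if mplug is None:
        raise SBMLReadError("SBML model lacks the fbc package (gene products)")

    model = Model(id=sbml_model.getId() or "model")

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
            Metabolite(
                id=sp.getId(),
                name=sp.getName(),
                compartment=sp.getCompartment(),
                formula=formula,
                charge=charge,
            )
        )

    for i in range(mplug.getNumGeneProducts()):
        gp = mplug.getGeneProduct(i)
        gid = gp.getId()
        model.add_gene(
            Gene(
                id=gid,
                name=gp.getName() or gp.getLabel(),
                origin=infer_origin(gid),
            )
        )
    _link_allele_partners(model)

    objective_rxn = None
    active = mplug.getActiveObjective()
    if active is not None and active.getNumFluxObjectives() > 0:
        objective_rxn = active.getFluxObjective(0).getReaction()

    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(rxn.getNumReactants()):
            ref = rxn.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(rxn.getNumProducts()):
            ref = rxn.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        rplug = rxn.getPlugin("fbc")
        lb, ub = 0.0, DEFAULT_UPPER_BOUND
        if rplug is not None:
            lb_param = sbml_model.getParameter(rplug.getLowerFluxBound())
            ub_param = sbml_model.getParameter(rplug.getUpperFluxBound())
            if lb_param is not None:
                lb = lb_param.getValue()
            if ub_param is not None:
                ub = ub_param.getValue()
        gpr = None
        if rplug is not None and rplug.isSetGeneProductAssociation():
            gpr = _association_to_gpr(
                rplug.getGeneProductAssociation().getAssociation()
            )
            undeclared = genes_of(gpr) - set(model.genes)
            if undeclared:
                raise SBMLReadError(
                    f"reaction {rxn.getId()!r} GPR references undeclared gene "
                    f"products: {sorted(undeclared)}"
                )
        sbo = rxn.getSBOTermID() if rxn.isSetSBOTerm() else None
        model.add_reaction(
            Reaction(
                id=rxn.getId(),
                name=rxn.getName(),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=gpr,
                sbo_term=sbo,
            )
        )

    model.objective_reaction_id = objective_rxn
    model.validate()
    return model


def _check(status: int, what: str) -> None:
    if status != libsbml.LIBSBML_OPERATION_SUCCESS:
        raise RuntimeError(f"libsbml call failed while setting {what}: {status}")


def write_sbml(model: Model, path: str) -> None:
    """Write ``model`` as SBML L3V1 + fbc v2 to ``path``.

    GPRs are serialized as fbc gene-product associations; reactions
    without a GPR get no association element.  Bounds are emitted as
    shared constant parameters, one per distinct value.
    """
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    _check(sm.setId(model.id), "model id")
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)

    compartments = sorted({m.compartment for m in model.metabolites.values()})
    for comp_id in compartments or ["c"]:
        comp = sm.createCompartment()
        _check(comp.setId(comp_id), f"compartment {comp_id!r}")
        comp.setConstant(True)

    for met in model.metabolites.values():
        sp = sm.createSpecies()
        _check(sp.setId(met.id), f"metabolite id {met.id!r}")
        sp.setName(met.name)
        sp.setCompartment(met.compartment)
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        splug = sp.getPlugin("fbc")
        if met.formula is not None:
            splug.setChemicalFormula(format_formula(met.formula))
        if met.charge is not None:
            splug.setCharge(met.charge)

    for gene in model.genes.values():
        gp = mplug.createGeneProduct()
        _check(gp.setId(gene.id), f"gene id {gene.id!r}")
        gp.setLabel(gene.id)
        if gene.name:
            gp.setName(gene.name)

    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            param = sm.createParameter()
            _check(param.setId(pid), f"bound parameter {pid}")
            param.setValue(value)
            param.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions.values():
        if not isinstance(rxn.gpr, (GPRNode, type(None))):
            raise ModelValidationError(
                f"reaction {rxn.id!r} carries a non-serializable GPR sentinel; "
                "prune the model before writing"
            )
        sr = sm.createReaction()
        _check(sr.setId(rxn.id), f"reaction id {rxn.id!r}")
        sr.setName(rxn.name)
        sr.setReversible(rxn.reversible)
        sr.setFast(False)
        if rxn.sbo_term:
            sr.setSBOTerm(rxn.sbo_term)
        for met_id, coeff in rxn.stoichiometry.items():
            if coeff < 0:
                ref = sr.createReactant()
                ref.setSpecies(met_id)
                ref.setStoichiometry(-coeff)
            elif coeff > 0:
                ref = sr.createProduct()
                ref.setSpecies(met_id)
                ref.setStoichiometry(coeff)
            else:
                continue
            ref.setConstant(True)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound))
        if rxn.gpr is not None:
            gpa = rplug.createGeneProductAssociation()
            status = gpa.setAssociation(format_gpr(rxn.gpr), True, False)
            _check(status, f"GPR of reaction {rxn.id!r}")

    if model.objective_reaction_id is not None:
        obj = mplug.createObjective()
        _check(obj.setId("obj"), "objective id")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(model.objective_reaction_id)
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise OSError(f"could not write SBML to {path!r}")
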