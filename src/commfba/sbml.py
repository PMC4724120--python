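"""SBML import/export for stoichiometric models.

Reads SBML Level 2 and Level 3 files.  Flux bounds are taken from the fbc
package where present, otherwise from kinetic-law parameters named
``LOWER_BOUND`` / ``UPPER_BOUND`` (the pre-fbc COBRA convention).  When a
reaction carries no bound at all, COBRA defaults are applied and logged:
(-1000, 1000) for reversible reactions, (0, 1000) otherwise.

Boundary metabolites are recognized by ``boundaryCondition="true"`` or by
membership in a designated environment compartment.
"""

from __future__ import annotations

import logging
from typing import Sequence

import libsbml

from .core import Metabolite, ModelConsistencyError, Reaction, StoichiometricModel

logger = logging.getLogger(__name__)

DEFAULT_UB = 1000.0
DEFAULT_LB_REVERSIBLE = -1000.0

#: Compartment ids whose species are treated as boundary metabolites.
ENV_COMPARTMENTS = ("environment", "env", "external")


class SbmlParseError(ValueError):
    """The SBML document is malformed; the message names the element."""


def _reaction_bounds(model, rxn, fbc_rxn):
    """Return (lb, ub, defaulted) for one SBML reaction."""
    lb = ub = None
    if fbc_rxn is not None:
        lb_id = fbc_rxn.getLowerFluxBound()
        ub_id = fbc_rxn.getUpperFluxBound()
        if lb_id:
            p = model.getParameter(lb_id)
            if p is not None:
                lb = p.getValue()
        if ub_id:
            p = model.getParameter(ub_id)
            if p is not None:
                ub = p.getValue()
    if lb is None or ub is None:
        kl = rxn.getKineticLaw()
        if kl is not None:
            for name, setter in (("LOWER_BOUND", "lb"), ("UPPER_BOUND", "ub")):
                p = kl.getParameter(name)
                if p is None and kl.getNumLocalParameters():
                    p = kl.getLocalParameter(name)
                if p is not None:
                    if setter == "lb" and lb is None:
                        lb = p.getValue()
                    elif setter == "ub" and ub is None:
                        ub = p.getValue()
    defaulted = lb is None and ub is None
    if lb is None:
        lb = DEFAULT_LB_REVERSIBLE if rxn.getReversible() else 0.0
    if ub is None:
        ub = DEFAULT_UB
    return lb, ub, defaulted


def load_sbml(
    path, env_compartments: Sequence[str] = ENV_COMPARTMENTS
) -> StoichiometricModel:
    """Read an SBML file into a :class:`StoichiometricModel`.

    Raises :class:`SbmlParseError` naming the offending element on malformed
    input.  Every reaction whose bounds had to be defaulted is logged as a
    warning.
    """
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors():
        for i in range(doc.getNumErrors()):
            err = doc.getError(i)
            if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
                raise SbmlParseError(
                    f"{path}: line {err.getLine()}: {err.getMessage()}"
                )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise SbmlParseError(f"{path}: document contains no <model> element")

    model = StoichiometricModel(sbml_model.getId() or "model")
    for sp in sbml_model.getListOfSpecies():
        boundary = sp.getBoundaryCondition() or sp.getCompartment() in env_compartments
        model.add_metabolite(
            Metabolite(
                id=sp.getId(),
                name=sp.getName(),
                compartment=sp.getCompartment(),
                is_boundary=bool(boundary),
            )
        )

    fbc_model = sbml_model.getPlugin("fbc")
    for rxn in sbml_model.getListOfReactions():
        stoich = {}
        for ref in rxn.getListOfReactants():
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for ref in rxn.getListOfProducts():
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        fbc_rxn = rxn.getPlugin("fbc")
        lb, ub, defaulted = _reaction_bounds(sbml_model, rxn, fbc_rxn)
        if defaulted:
            logger.warning(
                "reaction %r carries no flux bounds; defaulting to (%g, %g)",
                rxn.getId(), lb, ub,
            )
        model.add_reaction(
            Reaction(
                id=rxn.getId(),
                stoichiometry=stoich,
                lb=lb,
                ub=ub,
                reversible=bool(rxn.getReversible()) or lb < 0,
                name=rxn.getName(),
            )
        )

    if fbc_model is not None and fbc_model.getNumObjectives():
        active = fbc_model.getActiveObjective() or fbc_model.getObjective(0)
        if active is not None:
            for fo in active.getListOfFluxObjectives():
                model.objective[fo.getReaction()] = fo.getCoefficient()
    return model


def write_sbml(model: StoichiometricModel, path) -> None:
    """Write the model as SBML Level 3 with fbc flux bounds and objective."""
    ns = libsbml.SBMLNamespaces(3, 1)
    ns.addPackageNamespace("fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(model.id or "model")
    fbc_model = sbml_model.getPlugin("fbc")
    fbc_model.setStrict(False)

    compartments = {}
    for met in model.metabolites.values():
        if met.compartment not in compartments:
            comp = sbml_model.createCompartment()
            comp.setId(met.compartment)
            comp.setConstant(True)
            comp.setSize(1.0)
            compartments[met.compartment] = comp
        sp = sbml_model.createSpecies()
        sp.setId(met.id)
        sp.setName(met.name or met.id)
        sp.setCompartment(met.compartment)
        sp.setBoundaryCondition(bool(met.is_boundary))
        sp.setHasOnlySubstanceUnits(False)
        sp.setConstant(False)

    def _bound_param(value: float, tag: str) -> str:
        pid = f"fb_{tag}"
        p = sbml_model.createParameter()
        p.setId(pid)
        p.setValue(value)
        p.setConstant(True)
        return pid

    for rxn in model.reactions.values():
        srxn = sbml_model.createReaction()
        srxn.setId(rxn.id)
        srxn.setName(rxn.name or rxn.id)
        srxn.setReversible(bool(rxn.reversible))
        srxn.setFast(False)
        for mid, coef in rxn.stoichiometry.items():
            if coef < 0:
                ref = srxn.createReactant()
                ref.setStoichiometry(-coef)
            elif coef > 0:
                ref = srxn.createProduct()
                ref.setStoichiometry(coef)
            else:
                continue
            ref.setSpecies(mid)
            ref.setConstant(True)
        fbc_rxn = srxn.getPlugin("fbc")
        fbc_rxn.setLowerFluxBound(_bound_param(rxn.lb, f"{rxn.id}_lb"))
        fbc_rxn.setUpperFluxBound(_bound_param(rxn.ub, f"{rxn.id}_ub"))

    if model.objective:
        obj = fbc_model.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        for rid, coef in model.objective.items():
            fo = obj.createFluxObjective()
            fo.setReaction(rid)
            fo.setCoefficient(coef)
        fbc_model.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"could not write SBML to {path!r}")
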