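"""SBML Level 3 (FBC package) model reader and writer.

Bounds and stoichiometries travel as doubles in SBML; they are converted to
exact rationals through their shortest decimal representation, so decimal
data (the common case in published models) round-trips exactly.  Bounds of
+-INF map to unbounded.  GPR associations are converted to/from infix
``and``/``or`` strings.
"""

from __future__ import annotations

import math
from fractions import Fraction

import libsbml

from ._rational import Bound, to_rational
from .netmodel import ModelFormatError, Reaction, Species, StoichModel

__all__ = ["read_sbml", "write_sbml"]


def _from_double(x: float) -> Bound:
    if x is None or math.isnan(x):
        return None
    if math.isinf(x):
        return None
    return to_rational(float(x))


def read_sbml(path: str) -> StoichModel:
    doc = libsbml.readSBMLFromFile(path)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelFormatError(
            f"{path}: SBML parse error: {err.getMessage().strip()}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelFormatError(f"{path}: no model element")
    fbc = sbml_model.getPlugin("fbc")

    species = []
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        species.append(Species(sp.getId(), bool(sp.getBoundaryCondition())))

    params = {}
    for i in range(sbml_model.getNumParameters()):
        p = sbml_model.getParameter(i)
        params[p.getId()] = _from_double(p.getValue())

    obj_coeffs: dict[str, Fraction] = {}
    if fbc is not None and fbc.getNumObjectives() > 0:
        active = fbc.getActiveObjective() or fbc.getObjective(0)
        for i in range(active.getNumFluxObjectives()):
            fo = active.getFluxObjective(i)
            coeff = to_rational(float(fo.getCoefficient()))
            obj_coeffs[fo.getReaction()] = coeff

    reactions = []
    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        stoich: dict[str, Fraction] = {}
        for k in range(rx.getNumReactants()):
            ref = rx.getReactant(k)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), Fraction(0)) \
                - to_rational(float(ref.getStoichiometry()))
        for k in range(rx.getNumProducts()):
            ref = rx.getProduct(k)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), Fraction(0)) \
                + to_rational(float(ref.getStoichiometry()))
        stoich = {s: c for s, c in stoich.items() if c != 0}
        reversible = bool(rx.getReversible())
        lb: Bound = None if reversible else Fraction(0)
        ub: Bound = None
        gpr = None
        rplug = rx.getPlugin("fbc")
        if rplug is not None:
            lb_id = rplug.getLowerFluxBound()
            ub_id = rplug.getUpperFluxBound()
            if lb_id:
                if lb_id not in params:
                    raise ModelFormatError(
                        f"{path}: reaction {rx.getId()!r} references missing "
                        f"bound parameter {lb_id!r}"
                    )
                lb = params[lb_id]
            if ub_id:
                if ub_id not in params:
                    raise ModelFormatError(
                        f"{path}: reaction {rx.getId()!r} references missing "
                        f"bound parameter {ub_id!r}"
                    )
                ub = params[ub_id]
            gpa = rplug.getGeneProductAssociation()
            if gpa is not None and gpa.getAssociation() is not None:
                gpr = _association_to_infix(gpa.getAssociation())
        reactions.append(Reaction(
            id=rx.getId(),
            stoichiometry=stoich,
            reversible=reversible,
            lower_bound=lb,
            upper_bound=ub,
            objective_coeff=obj_coeffs.get(rx.getId(), Fraction(0)),
            gpr=gpr,
        ))
    model = StoichModel(species, reactions,
                        name=sbml_model.getId() or path)
    model.validate()
    return model


def _association_to_infix(assoc) -> str:
    if assoc.isGeneProductRef():
        return assoc.getGeneProduct()
    parts = [_association_to_infix(assoc.getAssociation(i))
             for i in range(assoc.getNumAssociations())]
    op = " and " if assoc.isFbcAnd() else " or "
    return "(" + op.join(parts) + ")"


def write_sbml(model: StoichModel, path: str) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(_sanitize(model.name))
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)

    comp = sm.createCompartment()
    comp.setId("c")
    comp.setConstant(True)

    for sp in model.species:
        s = sm.createSpecies()
        s.setId(_sanitize(sp.id))
        s.setCompartment("c")
        s.setBoundaryCondition(sp.is_boundary)
        s.setHasOnlySubstanceUnits(False)
        s.setConstant(False)

    def bound_param(value: Bound, default_inf: float) -> str:
        v = default_inf if value is None else float(value)
        pid = f"bnd_{len(bound_ids)}"
        for existing, pv in bound_ids.items():
            if pv == v:
                return existing
        p = sm.createParameter()
        p.setId(pid)
        p.setValue(v)
        p.setConstant(True)
        bound_ids[pid] = v
        return pid

    bound_ids: dict[str, float] = {}
    objective = mplug.createObjective()
    objective.setId("obj")
    objective.setType("maximize")
    mplug.setActiveObjectiveId("obj")
    genes: set[str] = set()

    for r in model.reactions:
        rx = sm.createReaction()
        rx.setId(_sanitize(r.id))
        rx.setReversible(r.reversible)
        rx.setFast(False)
        for sid, coeff in r.stoichiometry.items():
            ref = rx.createReactant() if coeff < 0 else rx.createProduct()
            ref.setSpecies(_sanitize(sid))
            ref.setStoichiometry(abs(float(coeff)))
            ref.setConstant(True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(r.lower_bound, -math.inf))
        rplug.setUpperFluxBound(bound_param(r.upper_bound, math.inf))
        if r.objective_coeff != 0:
            fo = objective.createFluxObjective()
            fo.setReaction(_sanitize(r.id))
            fo.setCoefficient(float(r.objective_coeff))
        if r.gpr:
            gpa = rplug.createGeneProductAssociation()
            gpa.setAssociation(r.gpr, True, True)
            from .objectives import _gpr_proteins, _parse_gpr

            genes |= _gpr_proteins(_parse_gpr(r.gpr))
    for g in sorted(genes):
        gp = mplug.getGeneProductByLabel(g)
        if gp is None:
            gp = mplug.createGeneProduct()
            gp.setId(_sanitize(g))
            gp.setLabel(g)

    if libsbml.writeSBMLToFile(doc, path) != 1:
        raise IOError(f"failed to write SBML to {path}")


def _sanitize(sid: str) -> str:
    out = "".join(ch if ch.isalnum() or ch == "_" else "_" for ch in sid)
    if not out or not (out[0].isalpha() or out[0] == "_"):
        out = "x_" + out
    return out
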