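"""Model I/O: a plain TSV triplet and SBML.

TSV dialect: a directory holding ``metabolites.tsv``, ``reactions.tsv``
and ``genes.tsv`` with fixed headers; stoichiometry is serialized as
``met:coeff;met:coeff`` with metabolites sorted by id, so write-read-write
round trips are byte-identical.

SBML: Level 3 with the fbc package (flux bounds as global parameters,
gene products, an active maximization objective).  Level 2 files carrying
LOWER_BOUND/UPPER_BOUND kinetic-law parameters are also read; when an L2
reaction states no bounds at all they default from its ``reversible``
flag, with a logged warning.  Unknown annotations are ignored (logged).
"""

from __future__ import annotations

import logging
import os
from pathlib import Path
from typing import Optional

from .gpr import parse_gpr
from .model import (
    DEFAULT_BOUND,
    Compartment,
    Gene,
    MetabolicModel,
    Metabolite,
    ModelIntegrityError,
    Reaction,
    ReactionKind,
)

logger = logging.getLogger(__name__)

_MET_HEADER = ["id", "name", "compartment"]
_RXN_HEADER = [
    "id",
    "name",
    "stoichiometry",
    "lower_bound",
    "upper_bound",
    "gpr",
    "subsystem",
    "kind",
    "objective",
]
_GENE_HEADER = ["id", "name"]


# ----------------------------------------------------------------- TSV


def _fmt(x: float) -> str:
    return repr(float(x))


def _serialize_stoich(stoich) -> str:
    return ";".join(f"{m}:{_fmt(c)}" for m, c in sorted(stoich.items()))


def _parse_stoich(text: str, rxn_id: str):
    out = {}
    for part in text.split(";"):
        if not part:
            continue
        try:
            met, coeff = part.rsplit(":", 1)
            out[met] = float(coeff)
        except ValueError:
            raise ModelIntegrityError(
                f"reaction {rxn_id!r}: cannot parse stoichiometry term {part!r}"
            ) from None
    return out


def write_model_tsv(model: MetabolicModel, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "metabolites.tsv", "w") as fh:
        fh.write("\t".join(_MET_HEADER) + "\n")
        for m in model.metabolites:
            fh.write(f"{m.id}\t{m.name}\t{m.compartment.value}\n")
    with open(directory / "reactions.tsv", "w") as fh:
        fh.write("\t".join(_RXN_HEADER) + "\n")
        for r in model.reactions:
            objective = "1" if r.id == model.objective_id else "0"
            fh.write(
                "\t".join(
                    [
                        r.id,
                        r.name,
                        _serialize_stoich(r.stoichiometry),
                        _fmt(r.lower_bound),
                        _fmt(r.upper_bound),
                        r.gpr,
                        r.subsystem,
                        r.kind.value,
                        objective,
                    ]
                )
                + "\n"
            )
    with open(directory / "genes.tsv", "w") as fh:
        fh.write("\t".join(_GENE_HEADER) + "\n")
        for g in model.genes:
            fh.write(f"{g.id}\t{g.name}\n")


def _read_rows(path: Path, header):
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].split("\t") != header:
        raise ModelIntegrityError(f"{path}: expected header {header}")
    return [line.split("\t") for line in lines[1:] if line]


def read_model_tsv(directory) -> MetabolicModel:
    directory = Path(directory)
    model = MetabolicModel(id=directory.name)
    for row in _read_rows(directory / "metabolites.tsv", _MET_HEADER):
        model.add_metabolite(Metabolite(id=row[0], name=row[1], compartment=row[2]))
    for row in _read_rows(directory / "genes.tsv", _GENE_HEADER):
        model.genes.append(Gene(id=row[0], name=row[1]))
    for row in _read_rows(directory / "reactions.tsv", _RXN_HEADER):
        rid = row[0]
        if row[3] == "" or row[4] == "":
            raise ModelIntegrityError(f"reaction {rid!r} is missing flux bounds")
        rxn = Reaction(
            id=rid,
            name=row[1],
            stoichiometry=_parse_stoich(row[2], rid),
            lower_bound=float(row[3]),
            upper_bound=float(row[4]),
            gpr=row[5],
            subsystem=row[6],
            kind=row[7],
        )
        parse_gpr(rxn.gpr)  # fail fast on malformed rules
        model.add_reaction(rxn)
        if row[8] == "1":
            model.objective_id = rid
    model.validate()
    return model


# ---------------------------------------------------------------- SBML

_COMPARTMENT_SBML = {
    Compartment.INTRACELLULAR: "c",
    Compartment.EXTRACELLULAR: "e",
}
_COMPARTMENT_FROM_SBML = {v: k for k, v in _COMPARTMENT_SBML.items()}


def _check(call, what: str):
    import libsbml

    if call is None or (isinstance(call, int) and call != libsbml.LIBSBML_OPERATION_SUCCESS):
        raise RuntimeError(f"SBML error while {what}: {call}")
    return call


def write_model_sbml(model: MetabolicModel, path) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(model.id or "model")
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)

    for cid, cname in (("c", "cytosol"), ("e", "extracellular")):
        comp = sm.createCompartment()
        comp.setId(cid)
        comp.setName(cname)
        comp.setConstant(True)

    for met in model.metabolites:
        s = sm.createSpecies()
        _check(s.setId(met.id), f"writing species {met.id}")
        s.setName(met.name or met.id)
        s.setCompartment(_COMPARTMENT_SBML[met.compartment])
        s.setHasOnlySubstanceUnits(False)
        s.setBoundaryCondition(False)
        s.setConstant(False)

    for gene in model.genes:
        gp = mplug.createGeneProduct()
        _check(gp.setId(gene.id), f"writing gene {gene.id}")
        gp.setLabel(gene.name or gene.id)

    bound_params = {}

    def _bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions:
        r = sm.createReaction()
        _check(r.setId(rxn.id), f"writing reaction {rxn.id}")
        r.setName(rxn.name or rxn.id)
        r.setReversible(rxn.lower_bound < 0)
        r.setFast(False)
        for met_id, coeff in sorted(rxn.stoichiometry.items()):
            if coeff < 0:
                sr = r.createReactant()
            else:
                sr = r.createProduct()
            sr.setSpecies(met_id)
            sr.setStoichiometry(abs(coeff))
            sr.setConstant(True)
        rplug = r.getPlugin("fbc")
        rplug.setLowerFluxBound(_bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(_bound_param(rxn.upper_bound))
        if rxn.gpr:
            gpa = rplug.createGeneProductAssociation()
            _check(gpa.setAssociation(rxn.gpr), f"writing GPR of {rxn.id}")

    if model.objective_id is not None:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(model.objective_id)
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    libsbml.writeSBMLToFile(doc, str(path))


def _infer_kind(rxn: Reaction, model: MetabolicModel, objective_id) -> ReactionKind:
    comps = {model.metabolite(m).compartment for m in rxn.stoichiometry}
    if rxn.id == objective_id:
        return ReactionKind.BIOMASS
    if len(rxn.stoichiometry) == 1 and comps == {Compartment.EXTRACELLULAR}:
        return ReactionKind.EXCHANGE
    if rxn.id.upper() == "ATPM":
        return ReactionKind.NGAM
    if len(comps) == 2:
        return ReactionKind.TRANSPORT
    if comps == {Compartment.EXTRACELLULAR}:
        return ReactionKind.EXTRACELLULAR
    return ReactionKind.INTRACELLULAR


def read_model_sbml(path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelIntegrityError(f"cannot parse SBML {path}: {err.getMessage()}")
    sm = doc.getModel()
    if sm is None:
        raise ModelIntegrityError(f"{path}: no model element")
    mplug = sm.getPlugin("fbc")

    model = MetabolicModel(id=sm.getId() or Path(str(path)).stem)
    for i in range(sm.getNumSpecies()):
        s = sm.getSpecies(i)
        comp = _COMPARTMENT_FROM_SBML.get(s.getCompartment())
        if comp is None:
            # anything that is not the canonical exterior is treated as inside
            comp = (
                Compartment.EXTRACELLULAR
                if s.getCompartment().lower().startswith("e")
                else Compartment.INTRACELLULAR
            )
        model.add_metabolite(Metabolite(id=s.getId(), name=s.getName(), compartment=comp))

    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            model.genes.append(Gene(id=gp.getId(), name=gp.getLabel()))

    objective_id = None
    if mplug is not None and mplug.getActiveObjective() is not None:
        obj = mplug.getActiveObjective()
        if obj.getNumFluxObjectives() > 0:
            objective_id = obj.getFluxObjective(0).getReaction()

    params = {
        sm.getParameter(i).getId(): sm.getParameter(i).getValue()
        for i in range(sm.getNumParameters())
    }

    for i in range(sm.getNumReactions()):
        r = sm.getReaction(i)
        stoich = {}
        for j in range(r.getNumReactants()):
            sr = r.getReactant(j)
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) - sr.getStoichiometry()
        for j in range(r.getNumProducts()):
            sr = r.getProduct(j)
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) + sr.getStoichiometry()
        stoich = {m: c for m, c in stoich.items() if c != 0}

        rplug = r.getPlugin("fbc")
        lb = ub = None
        if rplug is not None and rplug.isSetLowerFluxBound():
            lb = params.get(rplug.getLowerFluxBound())
            ub = params.get(rplug.getUpperFluxBound())
            if lb is None or ub is None:
                raise ModelIntegrityError(
                    f"reaction {r.getId()!r}: flux-bound parameter is missing"
                )
        elif r.isSetKineticLaw():
            kl = r.getKineticLaw()
            plb = kl.getParameter("LOWER_BOUND")
            pub = kl.getParameter("UPPER_BOUND")
            if plb is not None and pub is not None:
                lb, ub = plb.getValue(), pub.getValue()
        if lb is None or ub is None:
            if doc.getLevel() >= 3 and mplug is not None:
                raise ModelIntegrityError(
                    f"reaction {r.getId()!r} lacks flux bounds"
                )
            lb = -DEFAULT_BOUND if r.getReversible() else 0.0
            ub = DEFAULT_BOUND
            logger.warning(
                "reaction %s: no bounds stated, defaulting to (%g, %g)",
                r.getId(), lb, ub,
            )

        gpr = ""
        if rplug is not None and rplug.isSetGeneProductAssociation():
            assoc = rplug.getGeneProductAssociation().getAssociation()
            if assoc is not None:
                gpr = assoc.toInfix()

        rxn = Reaction(
            id=r.getId(),
            name=r.getName(),
            stoichiometry=stoich,
            lower_bound=float(lb),
            upper_bound=float(ub),
            gpr=gpr,
        )
        model.add_reaction(rxn)

    model.objective_id = objective_id
    for rxn in model.reactions:
        rxn.kind = _infer_kind(rxn, model, objective_id)
    model.validate()
    return model


# ---------------------------------------------------------------- API


def read_model(path, format: Optional[str] = None) -> MetabolicModel:
    """Read a model from SBML (a file) or the TSV triplet (a directory)."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such model file or directory: {path}")
    if format is None:
        format = "tsv" if os.path.isdir(path) else "sbml"
    if format == "sbml":
        return read_model_sbml(path)
    if format == "tsv":
        return read_model_tsv(path)
    raise ValueError(f"unknown model format {format!r}")


def write_model(model: MetabolicModel, path, format: Optional[str] = None) -> None:
    if format is None:
        format = "sbml" if str(path).endswith((".xml", ".sbml")) else "tsv"
    if format == "sbml":
        write_model_sbml(model, path)
    elif format == "tsv":
        write_model_tsv(model, path)
    else:
        raise ValueError(f"unknown model format {format!r}")
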