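"""SBML Level 3 (+fbc) and spreadsheet serialization of metabolic models.

Writers follow community conventions: identifiers are sanitized to SBML SIds
with ``R_``/``M_``/``G_`` prefixes (a mapping table is returned), every gene
product carries SBO:0000243, every reaction SBO:0000375 and every species
SBO:0000247; EC links are attached as identifiers.org ``ec-code`` resource
annotations and reconstruction provenance / gap-fill penalties go into the
element notes. A single default compartment ``c`` holds all species.
"""

from __future__ import annotations

import re
import warnings
from typing import Mapping

import libsbml

from .model import MetabolicModel, Reaction

__all__ = ["write_sbml", "read_sbml", "write_tabular"]

SBO_GENE = "SBO:0000243"
SBO_REACTION = "SBO:0000375"
SBO_SPECIES = "SBO:0000247"

_SID_BAD = re.compile(r"[^A-Za-z0-9_]")


def _sanitize(raw: str, prefix: str) -> str:
    return prefix + _SID_BAD.sub("_", raw)


def _check(code, what: str) -> None:
    if code is not None and isinstance(code, int) and code < 0:
        raise RuntimeError(f"libsbml error while {what}: code {code}")


def _notes(pairs: Mapping[str, object]) -> str:
    body = "".join(f"<p>{k}: {v}</p>" for k, v in pairs.items())
    return (
        '<body xmlns="http://www.w3.org/1999/xhtml">' + body + "</body>"
    )


def write_sbml(model: MetabolicModel, path) -> dict[str, str]:
    """Write an SBML L3V1 document with the fbc package.

    Returns the sanitization mapping ``{sbml_id: original_id}``. A model
    without an objective is written with a warning and no objective element.
    """
    model.validate()
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(_SID_BAD.sub("_", model.id) or "model")
    fbc = sbml_model.getPlugin("fbc")
    fbc.setStrict(True)

    mapping: dict[str, str] = {}

    comp = sbml_model.createCompartment()
    comp.setId("c")
    comp.setConstant(True)

    met_ids: dict[str, str] = {}
    for met in model.metabolites:
        sid = _sanitize(met, "M_")
        met_ids[met] = sid
        mapping[sid] = met
        sp = sbml_model.createSpecies()
        _check(sp.setId(sid), f"species id {sid}")
        sp.setName(met)
        sp.setCompartment("c")
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        sp.setInitialConcentration(0.0)
        sp.setSBOTerm(SBO_SPECIES)

    gene_ids: dict[str, str] = {}
    for gene in sorted(model.genes):
        gid = _sanitize(gene, "G_")
        gene_ids[gene] = gid
        mapping[gid] = gene
        gp = fbc.createGeneProduct()
        _check(gp.setId(gid), f"gene product id {gid}")
        gp.setLabel(gene)
        gp.setSBOTerm(SBO_GENE)

    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            par = sbml_model.createParameter()
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rid, rxn in model.reactions.items():
        sid = _sanitize(rid, "R_")
        mapping[sid] = rid
        sr = sbml_model.createReaction()
        _check(sr.setId(sid), f"reaction id {sid}")
        sr.setName(rxn.name or rid)
        sr.setReversible(rxn.reversible)
        sr.setFast(False)
        sr.setSBOTerm(SBO_REACTION)
        for met, coef in rxn.stoichiometry.items():
            ref = sr.createReactant() if coef < 0 else sr.createProduct()
            ref.setSpecies(met_ids[met])
            ref.setStoichiometry(abs(float(coef)))
            ref.setConstant(True)
        rf = sr.getPlugin("fbc")
        rf.setLowerFluxBound(bound_param(float(rxn.lower_bound)))
        rf.setUpperFluxBound(bound_param(float(rxn.upper_bound)))

        genes = sorted(model.gene_associations.get(rid, ()))
        if genes:
            gpa = rf.createGeneProductAssociation()
            if len(genes) == 1:
                ref = gpa.createGeneProductRef()
                ref.setGeneProduct(gene_ids[genes[0]])
            else:
                gor = gpa.createOr()
                for g in genes:
                    ref = gor.createGeneProductRef()
                    ref.setGeneProduct(gene_ids[g])

        if rxn.ec_links:
            sr.setMetaId(f"meta_{sid}")
            for ec in sorted(rxn.ec_links):
                cv = libsbml.CVTerm()
                cv.setQualifierType(libsbml.BIOLOGICAL_QUALIFIER)
                cv.setBiologicalQualifierType(libsbml.BQB_IS)
                cv.addResource(f"https://identifiers.org/ec-code/{ec}")
                sr.addCVTerm(cv)
        note_fields: dict[str, object] = {"spontaneous": rxn.spontaneous}
        if rid in model.provenance:
            note_fields["provenance"] = model.provenance[rid]
        if rid in model.gapfill_penalties:
            note_fields["gapfill_penalty"] = repr(model.gapfill_penalties[rid])
        sr.setNotes(_notes(note_fields))

    if model.objective:
        obj = fbc.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        for rid, coef in model.objective.items():
            fo = obj.createFluxObjective()
            fo.setReaction(_sanitize(rid, "R_"))
            fo.setCoefficient(float(coef))
        fbc.setActiveObjectiveId("obj")
    else:
        warnings.warn("model has no objective; writing SBML without one", stacklevel=2)

    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        raise RuntimeError(doc.getErrorLog().toString())
    libsbml.writeSBMLToFile(doc, str(path))
    return mapping


def _strip(sid: str, prefix: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def _note_fields(element) -> dict[str, str]:
    out: dict[str, str] = {}
    if element.isSetNotes():
        text = element.getNotesString()
        for m in re.finditer(r"<p>\s*([^<:]+?)\s*:\s*(.*?)\s*</p>", text):
            out[m.group(1)] = m.group(2)
    return out


def read_sbml(path) -> MetabolicModel:
    """Read an SBML L3 (+fbc) document back into a :class:`MetabolicModel`.

    Round-trips documents written by :func:`write_sbml`: stoichiometry,
    bounds, gene associations, objective, EC links, provenance and gap-fill
    penalties are all recovered (identifier prefixes are stripped).
    """
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        raise ValueError(doc.getErrorLog().toString())
    if doc.getLevel() != 3:
        raise ValueError(f"unsupported SBML level {doc.getLevel()} (need Level 3)")
    sm = doc.getModel()
    fbc = sm.getPlugin("fbc")

    met_names = {
        sm.getSpecies(i).getId(): _strip(sm.getSpecies(i).getId(), "M_")
        for i in range(sm.getNumSpecies())
    }
    gene_labels: dict[str, str] = {}
    if fbc is not None:
        for i in range(fbc.getNumGeneProducts()):
            gp = fbc.getGeneProduct(i)
            gene_labels[gp.getId()] = gp.getLabel() or _strip(gp.getId(), "G_")

    params = {
        sm.getParameter(i).getId(): sm.getParameter(i).getValue()
        for i in range(sm.getNumParameters())
    }

    model = MetabolicModel(id=sm.getId() or "model")
    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        rid = _strip(sr.getId(), "R_")
        stoich: dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            met = met_names[ref.getSpecies()]
            stoich[met] = stoich.get(met, 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            met = met_names[ref.getSpecies()]
            stoich[met] = stoich.get(met, 0.0) + ref.getStoichiometry()

        rf = sr.getPlugin("fbc")
        lb = params.get(rf.getLowerFluxBound()) if rf is not None else None
        ub = params.get(rf.getUpperFluxBound()) if rf is not None else None

        ecs = set()
        for j in range(sr.getNumCVTerms()):
            cv = sr.getCVTerm(j)
            for k in range(cv.getNumResources()):
                uri = cv.getResourceURI(k)
                if "ec-code" in uri:
                    ecs.add(uri.rsplit("/", 1)[-1])

        notes = _note_fields(sr)
        rxn = Reaction(
            id=rid,
            stoichiometry=stoich,
            reversible=sr.getReversible(),
            ec_links=frozenset(ecs),
            spontaneous=notes.get("spontaneous", "False") == "True",
            lower_bound=lb,
            upper_bound=ub,
            name=sr.getName() or "",
        )
        genes: set[str] = set()
        if rf is not None and rf.isSetGeneProductAssociation():
            assoc = rf.getGeneProductAssociation().getAssociation()
            genes = {gene_labels.get(g, g) for g in _gene_refs(assoc)}
        model.add_reaction(rxn, genes=genes, provenance=notes.get("provenance"))
        if "gapfill_penalty" in notes:
            model.gapfill_penalties[rid] = float(notes["gapfill_penalty"])

    if fbc is not None and fbc.getNumObjectives():
        obj = fbc.getObjective(fbc.getActiveObjectiveId() or 0) or fbc.getObjective(0)
        for j in range(obj.getNumFluxObjectives()):
            fo = obj.getFluxObjective(j)
            model.objective[_strip(fo.getReaction(), "R_")] = fo.getCoefficient()
    model.validate()
    return model


def _gene_refs(assoc) -> list[str]:
    if assoc is None:
        return []
    if isinstance(assoc, libsbml.GeneProductRef):
        return [assoc.getGeneProduct()]
    out: list[str] = []
    for i in range(assoc.getNumAssociations()):
        out.extend(_gene_refs(assoc.getAssociation(i)))
    return out


def write_tabular(model: MetabolicModel, path) -> None:
    """Spreadsheet export: Reactions, Metabolites and Objective sheets."""
    import pandas as pd

    rows = []
    for rid, rxn in model.reactions.items():
        rows.append(
            {
                "reaction_id": rid,
                "name": rxn.name,
                "equation": rxn.equation(),
                "lower_bound": rxn.lower_bound,
                "upper_bound": rxn.upper_bound,
                "reversible": rxn.reversible,
                "genes": ";".join(sorted(model.gene_associations.get(rid, ()))),
                "ec_links": ";".join(sorted(rxn.ec_links)),
                "spontaneous": rxn.spontaneous,
                "provenance": model.provenance.get(rid, ""),
                "gapfill_penalty": model.gapfill_penalties.get(rid, ""),
            }
        )
    reactions = pd.DataFrame(rows)
    metabolites = pd.DataFrame({"metabolite_id": model.metabolites, "compartment": "c"})
    objective = pd.DataFrame(
        [{"reaction_id": rid, "coefficient": c} for rid, c in model.objective.items()]
    )
    with pd.ExcelWriter(path, engine="openpyxl") as xl:
        reactions.to_excel(xl, sheet_name="Reactions", index=False)
        metabolites.to_excel(xl, sheet_name="Metabolites", index=False)
        objective.to_excel(xl, sheet_name="Objective", index=False)
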