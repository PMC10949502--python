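"""Model readers and writers: native JSON dialect, SBML L3+FBC, TSV import.

The JSON dialect (schema in ``docs/model_schema.md``) is the native,
loss-free format: every field of the in-memory model round-trips exactly,
with deterministic key ordering so repeated writes are bit-stable.

SBML Level 3 + FBC is the interoperable format.  Ids are prefixed ``M_``/
``R_`` on write (SBML SIds cannot start with a digit) and stripped on read;
gene, subsystem and the pseudo flag travel in the reaction notes.  One
lossy corner: an explicitly empty formula map ({} = "no C, no N") and an
absent formula both come back as absent, since FBC has no empty chemical
formula.

TSV is import-only: an optional ``# metabolites`` section (id, name,
compartment, formula) followed by a ``# reactions`` section (id, equation,
lb, ub, gene, subsystem) with equations written ``a A + b B -> c C`` (or
``<=>`` for reversible display; bounds are authoritative).
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import libsbml

from .model import (
    DEFAULT_BOUND,
    Metabolite,
    MetabolicModel,
    ModelValidationError,
    Reaction,
)

__all__ = ["load_model", "write_model", "FormatError"]


class FormatError(ValueError):
    """The file does not parse in the named format."""


PathLike = Union[str, Path]


def load_model(path: PathLike, format: Optional[str] = None) -> MetabolicModel:
    """Load and validate a model from ``json``, ``sbml`` or ``tsv``."""
    path = Path(path)
    fmt = format or _guess_format(path)
    if fmt == "json":
        model = _read_json(path)
    elif fmt == "sbml":
        model = _read_sbml(path)
    elif fmt == "tsv":
        model = _read_tsv(path)
    else:
        raise ValueError(f"unknown model format {fmt!r}")
    model.validate()
    return model


def write_model(model: MetabolicModel, path: PathLike, format: Optional[str] = None) -> None:
    """Validate and write a model as ``json`` or ``sbml`` (TSV is import-only)."""
    model.validate()
    path = Path(path)
    fmt = format or _guess_format(path)
    if fmt == "json":
        _write_json(model, path)
    elif fmt == "sbml":
        _write_sbml(model, path)
    elif fmt == "tsv":
        raise ValueError("TSV is an import-only format")
    else:
        raise ValueError(f"unknown model format {fmt!r}")


def _guess_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".json":
        return "json"
    if suffix in (".xml", ".sbml"):
        return "sbml"
    if suffix in (".tsv", ".txt"):
        return "tsv"
    raise ValueError(f"cannot guess model format from {path.name!r}")


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def _read_json(path: Path) -> MetabolicModel:
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON: {exc}") from exc
    try:
        mets = [
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", "c"),
                formula=(None if m.get("formula") is None
                         else {k: int(v) for k, v in m["formula"].items()}),
            )
            for m in doc["metabolites"]
        ]
        rxns = [
            Reaction(
                id=r["id"],
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                lower_bound=float(r["lower_bound"]),
                upper_bound=float(r["upper_bound"]),
                name=r.get("name", ""),
                gene=r.get("gene"),
                subsystem=r.get("subsystem"),
                is_exchange=bool(r.get("is_exchange", False)),
                is_pseudo=bool(r.get("is_pseudo", False)),
            )
            for r in doc["reactions"]
        ]
        obj = doc["objective"]
        return MetabolicModel(
            id=doc["id"],
            metabolites=mets,
            reactions=rxns,
            objective_id=obj["reaction"],
            objective_sense=obj.get("sense", "maximize"),
            annotations=dict(doc.get("annotations", {})),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"{path}: malformed model document: {exc}") from exc


def _write_json(model: MetabolicModel, path: Path) -> None:
    doc = {
        "id": model.id,
        "objective": {"reaction": model.objective_id, "sense": model.objective_sense},
        "annotations": {k: model.annotations[k] for k in sorted(model.annotations)},
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": (None if m.formula is None
                            else {k: m.formula[k] for k in sorted(m.formula)}),
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": {k: r.stoichiometry[k] for k in sorted(r.stoichiometry)},
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene": r.gene,
                "subsystem": r.subsystem,
                "is_exchange": r.is_exchange,
                "is_pseudo": r.is_pseudo,
            }
            for r in model.reactions
        ],
    }
    path.write_text(json.dumps(doc, indent=1) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# TSV import
# ---------------------------------------------------------------------------

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")
_TERM_RE = re.compile(r"^(?:(\d+(?:\.\d+)?)\s+)?(\S+)$")


def _parse_formula(text: str) -> Optional[Dict[str, int]]:
    text = text.strip()
    if not text or text == "-":
        return None
    out: Dict[str, int] = {}
    pos = 0
    for match in _FORMULA_RE.finditer(text):
        if match.start() != pos:
            raise FormatError(f"bad formula string {text!r}")
        out[match.group(1)] = int(match.group(2) or 1)
        pos = match.end()
        if pos == len(text):
            break
    if pos != len(text):
        raise FormatError(f"bad formula string {text!r}")
    return out


def parse_equation(text: str) -> Dict[str, float]:
    """Parse ``a A + b B -> c C`` (or ``<=>``/``<->``) into signed stoichiometry."""
    for arrow in ("<=>", "<->", "->", "=>"):
        if arrow in text:
            left, right = text.split(arrow, 1)
            break
    else:
        raise FormatError(f"no reaction arrow in equation {text!r}")
    stoich: Dict[str, float] = {}

    def add(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split(" + "):
            term = term.strip()
            if not term:
                continue
            m = _TERM_RE.match(term)
            if not m:
                raise FormatError(f"bad equation term {term!r} in {text!r}")
            coeff = float(m.group(1)) if m.group(1) else 1.0
            met = m.group(2)
            stoich[met] = stoich.get(met, 0.0) + sign * coeff

    add(left, -1.0)
    add(right, +1.0)
    stoich = {k: v for k, v in stoich.items() if v != 0.0}
    if not stoich:
        raise FormatError(f"equation {text!r} has empty net stoichiometry")
    return stoich


def _read_tsv(path: Path) -> MetabolicModel:
    mets: List[Metabolite] = []
    rxns: List[Reaction] = []
    declared: Optional[set] = None
    section = "reactions"
    header: Optional[List[str]] = None
    objective_id = ""
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            tag = line.lstrip("#").strip().lower()
            if tag.startswith("metabolites"):
                section, header, declared = "metabolites", None, set()
            elif tag.startswith("reactions"):
                section, header = "reactions", None
            elif tag.startswith("objective"):
                objective_id = line.lstrip("#").strip().split()[-1]
            continue
        fields = line.split("\t")
        if header is None:
            header = [f.strip().lower() for f in fields]
            continue
        row = dict(zip(header, fields))
        if section == "metabolites":
            met = Metabolite(
                id=row["id"].strip(),
                name=row.get("name", "").strip(),
                compartment=row.get("compartment", "c").strip() or "c",
                formula=_parse_formula(row.get("formula", "")),
            )
            mets.append(met)
            declared.add(met.id)  # type: ignore[union-attr]
        else:
            try:
                stoich = parse_equation(row["equation"])
            except KeyError as exc:
                raise FormatError(f"{path}:{lineno}: missing column {exc}") from exc
            rid = row["id"].strip()
            if declared is not None:
                missing = sorted(m for m in stoich if m not in declared)
                if missing:
                    raise ModelValidationError(
                        f"{path}:{lineno}: reaction {rid!r} references "
                        "metabolite(s) absent from the species table: "
                        + ", ".join(repr(m) for m in missing)
                    )
            rxns.append(Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=float(row.get("lb", -DEFAULT_BOUND) or -DEFAULT_BOUND),
                upper_bound=float(row.get("ub", DEFAULT_BOUND) or DEFAULT_BOUND),
                gene=(row.get("gene", "").strip() or None),
                subsystem=(row.get("subsystem", "").strip() or None),
                is_exchange=len(stoich) == 1,
            ))
    if declared is None:
        # no species table: infer metabolites from equations
        seen: Dict[str, None] = {}
        for r in rxns:
            for m in r.stoichiometry:
                seen.setdefault(m, None)
        mets = [Metabolite(id=m) for m in seen]
    if not objective_id and rxns:
        objective_id = rxns[-1].id
    return MetabolicModel(
        id=path.stem, metabolites=mets, reactions=rxns, objective_id=objective_id
    )


# ---------------------------------------------------------------------------
# SBML Level 3 + FBC
# ---------------------------------------------------------------------------

def _formula_string(formula: Optional[Dict[str, int]]) -> Optional[str]:
    if not formula:  # None or {} -> no chemicalFormula attribute
        return None
    return "".join(f"{el}{formula[el]}" for el in sorted(formula))


def _write_sbml(model: MetabolicModel, path: Path) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(model.id)
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    compartments = sorted({m.compartment for m in model.metabolites})
    for comp in compartments:
        c = sbml_model.createCompartment()
        c.setId(comp)
        c.setConstant(True)

    for met in model.metabolites:
        s = sbml_model.createSpecies()
        s.setId("M_" + met.id)
        s.setName(met.name)
        s.setCompartment(met.compartment)
        s.setConstant(False)
        s.setBoundaryCondition(False)
        s.setHasOnlySubstanceUnits(False)
        formula = _formula_string(met.formula)
        if formula is not None:
            s.getPlugin("fbc").setChemicalFormula(formula)

    # bound parameters shared by value (keeps the file compact)
    bound_params: Dict[float, str] = {}

    def bound_parameter(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sbml_model.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions:
        r = sbml_model.createReaction()
        r.setId("R_" + rxn.id)
        r.setName(rxn.name)
        r.setReversible(rxn.lower_bound < 0)
        r.setFast(False)
        for met_id, coeff in sorted(rxn.stoichiometry.items()):
            if coeff < 0:
                ref = r.createReactant()
                ref.setStoichiometry(-coeff)
            else:
                ref = r.createProduct()
                ref.setStoichiometry(coeff)
            ref.setSpecies("M_" + met_id)
            ref.setConstant(True)
        rplug = r.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_parameter(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_parameter(rxn.upper_bound))
        notes = []
        if rxn.gene:
            notes.append(f"<p>gene: {rxn.gene}</p>")
        if rxn.subsystem:
            notes.append(f"<p>subsystem: {rxn.subsystem}</p>")
        if rxn.is_exchange:
            notes.append("<p>exchange: true</p>")
        if rxn.is_pseudo:
            notes.append("<p>pseudo: true</p>")
        if notes:
            r.setNotes(
                '<body xmlns="http://www.w3.org/1999/xhtml">'
                + "".join(notes) + "</body>"
            )

    objective = mplug.createObjective()
    objective.setId("obj")
    objective.setType("maximize" if model.objective_sense == "maximize" else "minimize")
    flux_obj = objective.createFluxObjective()
    flux_obj.setReaction("R_" + model.objective_id)
    flux_obj.setCoefficient(1.0)
    mplug.setActiveObjectiveId("obj")

    libsbml.writeSBMLToFile(doc, str(path))


_NOTE_RE = re.compile(r"<p>\s*([^:<]+):\s*([^<]*)</p>")


def _read_sbml(path: Path) -> MetabolicModel:
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msgs = [doc.getError(i).getMessage()
                for i in range(doc.getNumErrors())
                if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR]
        raise FormatError(f"{path}: SBML parse errors: " + "; ".join(msgs))
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise FormatError(f"{path}: no model element")

    def strip(sid: str, prefix: str) -> str:
        return sid[len(prefix):] if sid.startswith(prefix) else sid

    mets = []
    for i in range(sbml_model.getNumSpecies()):
        s = sbml_model.getSpecies(i)
        splug = s.getPlugin("fbc")
        formula = None
        if splug is not None and splug.isSetChemicalFormula():
            formula = _parse_formula(splug.getChemicalFormula())
        mets.append(Metabolite(
            id=strip(s.getId(), "M_"),
            name=s.getName() or "",
            compartment=s.getCompartment() or "c",
            formula=formula,
        ))

    params = {
        sbml_model.getParameter(i).getId(): sbml_model.getParameter(i).getValue()
        for i in range(sbml_model.getNumParameters())
    }

    rxns = []
    for i in range(sbml_model.getNumReactions()):
        r = sbml_model.getReaction(i)
        stoich: Dict[str, float] = {}
        for j in range(r.getNumReactants()):
            ref = r.getReactant(j)
            met = strip(ref.getSpecies(), "M_")
            stoich[met] = stoich.get(met, 0.0) - ref.getStoichiometry()
        for j in range(r.getNumProducts()):
            ref = r.getProduct(j)
            met = strip(ref.getSpecies(), "M_")
            stoich[met] = stoich.get(met, 0.0) + ref.getStoichiometry()
        rplug = r.getPlugin("fbc")
        lb = params.get(rplug.getLowerFluxBound(), -DEFAULT_BOUND)
        ub = params.get(rplug.getUpperFluxBound(), DEFAULT_BOUND)
        notes: Dict[str, str] = {}
        if r.isSetNotes():
            notes = {k.strip(): v.strip()
                     for k, v in _NOTE_RE.findall(r.getNotesString())}
        if "exchange" in notes:
            is_exchange = notes["exchange"] == "true"
        else:
            # third-party SBML without our notes: exchange-prefix heuristic
            is_exchange = len(stoich) == 1 and r.getId().startswith("R_EX_")
        rxns.append(Reaction(
            id=strip(r.getId(), "R_"),
            stoichiometry=stoich,
            lower_bound=lb,
            upper_bound=ub,
            name=r.getName() or "",
            gene=notes.get("gene"),
            subsystem=notes.get("subsystem"),
            is_exchange=is_exchange,
            is_pseudo=notes.get("pseudo") == "true",
        ))

    mplug = sbml_model.getPlugin("fbc")
    objective_id = ""
    sense = "maximize"
    if mplug is not None and mplug.getNumObjectives() > 0:
        obj = mplug.getObjective(mplug.getActiveObjectiveId()) or mplug.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            objective_id = strip(obj.getFluxObjective(0).getReaction(), "R_")
            sense = "maximize" if obj.getType() == "maximize" else "minimize"

    return MetabolicModel(
        id=sbml_model.getId() or path.stem,
        metabolites=mets,
        reactions=rxns,
        objective_id=objective_id,
        objective_sense=sense,
    )
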