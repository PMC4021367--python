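"""Readers and writers: SBML level 2 version 1, tabular reaction lists,
and media (exchange-bound) configuration files.

The tabular dialect is a 7-column TSV — reaction id, name, reaction
string, GPR string, subsystem, lower bound, upper bound — with reaction
strings written ``"L_ASP[c] + AKG[c] <=> L_GLU[c] + OAC[c]"``.  The
parser also tolerates the spaced arrow variants ``"< = >"`` and ``"- >"``
that appear in print; the serializer always emits the compact forms.

GPR rules travel inside SBML reaction notes as ``GENE_ASSOCIATION:``
lines (the pre-fbc convention for level 2 documents), flux bounds as
kinetic-law parameters ``LOWER_BOUND``/``UPPER_BOUND``, and the linear
objective as ``OBJECTIVE_COEFFICIENT``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd
import yaml

from .core import (DEFAULT_BOUND, SUBSYSTEMS, MetabolicModel, Metabolite,
                   ModelIntegrityError, Reaction)


def _coerce_subsystem(label: str) -> str:
    """Map free-text subsystem labels onto the canonical set.

    External models use arbitrary pathway names; anything unrecognized
    falls back to "carbohydrates" so loading never aborts on labels.
    """
    label = (label or "").strip().lower()
    return label if label in SUBSYSTEMS else "carbohydrates"
from .gpr import parse_gpr


class ReactionParseError(ValueError):
    pass


class SbmlDialectError(ValueError):
    pass


# ---------------------------------------------------------------------
# reaction strings
# ---------------------------------------------------------------------

_REV_ARROW = re.compile(r"<\s*=\s*>")
_IRR_ARROW = re.compile(r"-\s*>")
_TERM = re.compile(r"^(?:(\d+(?:\.\d+)?)\s+)?(\S.*)$")


def parse_reaction_string(text: str) -> Tuple[Dict[str, float], bool]:
    """Parse ``"substrates <=> products"`` into a stoichiometry map.

    Substrates get negative and products positive coefficients; an
    omitted coefficient means 1.  Returns (stoichiometry, reversible).
    """
    normalized = _REV_ARROW.sub("<=>", text)
    normalized = _IRR_ARROW.sub("->", normalized)
    if "<=>" in normalized:
        reversible = True
        sides = normalized.split("<=>")
    elif "->" in normalized:
        reversible = False
        sides = normalized.split("->")
    else:
        raise ReactionParseError(f"no reaction arrow in {text!r}")
    if len(sides) != 2:
        raise ReactionParseError(f"multiple arrows in {text!r}")

    stoich: Dict[str, float] = {}
    for sign, side in ((-1.0, sides[0]), (+1.0, sides[1])):
        seen = set()
        for raw in side.split("+"):
            term = raw.strip()
            if not term:
                continue
            m = _TERM.match(term)
            if m is None:
                raise ReactionParseError(f"bad term {term!r} in {text!r}")
            coeff = float(m.group(1)) if m.group(1) else 1.0
            met = m.group(2).strip()
            if met in seen:
                raise ReactionParseError(
                    f"metabolite {met!r} duplicated on one side of {text!r}")
            seen.add(met)
            if met in stoich:
                raise ReactionParseError(
                    f"metabolite {met!r} appears on both sides of {text!r}")
            stoich[met] = sign * coeff
    if not stoich:
        raise ReactionParseError(f"no metabolites in {text!r}")
    return stoich, reversible


def format_reaction_string(rxn: Reaction) -> str:
    """Serialize stoichiometry back to the compact text form."""
    def fmt(mid: str, coeff: float) -> str:
        mag = abs(coeff)
        if math.isclose(mag, 1.0, abs_tol=1e-12):
            return mid
        if math.isclose(mag, round(mag), abs_tol=1e-9):
            return f"{int(round(mag))} {mid}"
        return f"{mag:g} {mid}"

    subs = [fmt(m, c) for m, c in rxn.stoichiometry.items() if c < 0]
    prods = [fmt(m, c) for m, c in rxn.stoichiometry.items() if c > 0]
    arrow = "<=>" if rxn.reversible else "->"
    return f"{' + '.join(subs)} {arrow} {' + '.join(prods)}".strip()


# ---------------------------------------------------------------------
# media
# ---------------------------------------------------------------------

@dataclass
class MediumSpec:
    """A named environmental condition as exchange-flux bounds.

    ``bounds`` maps exchange reaction ids to (lower, upper) in mmol
    gDCW^-1 h^-1 (uptake negative); ids in ``unconstrained`` are opened
    to (-1000, 1000), e.g. water and mineral exchanges.  Exchanges in
    neither list are closed to uptake when the medium is applied.
    """

    name: str
    bounds: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    unconstrained: List[str] = field(default_factory=list)

    def __post_init__(self):
        for rid, (lb, ub) in self.bounds.items():
            if lb > ub:
                raise ValueError(
                    f"medium {self.name!r}: {rid} lower bound {lb} exceeds "
                    f"upper bound {ub}")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "bounds": {rid: [float(lb), float(ub)]
                       for rid, (lb, ub) in self.bounds.items()},
            "unconstrained": list(self.unconstrained),
        }


def read_medium(path: str | Path) -> MediumSpec:
    """Load a JSON/YAML medium file {name, bounds:{id:[lb,ub]}, unconstrained}.

    An empty file yields a closed medium (all exchanges uptake-blocked).
    Whether every id is really an exchange reaction is checked when the
    medium is applied to a model.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"medium file {path}: expected a mapping")
    bounds = {}
    for rid, pair in (raw.get("bounds") or {}).items():
        if not (isinstance(pair, (list, tuple)) and len(pair) == 2):
            raise ValueError(f"medium file {path}: bounds for {rid!r} must "
                             "be a [lower, upper] pair")
        bounds[rid] = (float(pair[0]), float(pair[1]))
    return MediumSpec(name=raw.get("name", Path(path).stem),
                      bounds=bounds,
                      unconstrained=list(raw.get("unconstrained") or []))


def write_medium(medium: MediumSpec, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(medium.to_dict(), sort_keys=False))


# ---------------------------------------------------------------------
# tabular reaction lists
# ---------------------------------------------------------------------

TABLE_COLUMNS = ["reaction_id", "name", "reaction", "gpr", "subsystem",
                 "lower_bound", "upper_bound"]


def read_reaction_table(path: str | Path,
                        model_id: Optional[str] = None,
                        objective_id: Optional[str] = None) -> MetabolicModel:
    """Build a model from the 7-column TSV reaction list.

    Blank bounds default by reversibility: (-1000, 1000) for ``<=>``,
    (0, 1000) for ``->``.  The objective defaults to the reaction whose
    id or subsystem says "biomass".
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    model = MetabolicModel(model_id or Path(path).stem)
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            stoich, reversible = parse_reaction_string(row.reaction)
        except ReactionParseError as exc:
            raise ReactionParseError(f"{path} row {row_no}: {exc}") from exc
        lb = float(row.lower_bound) if str(row.lower_bound).strip() else (
            -DEFAULT_BOUND if reversible else 0.0)
        ub = float(row.upper_bound) if str(row.upper_bound).strip() else (
            DEFAULT_BOUND)
        for mid in stoich:
            if mid not in model.metabolites:
                model.add_metabolite(Metabolite(mid))
        model.add_reaction(Reaction(
            id=row.reaction_id, stoichiometry=stoich, name=row.name,
            lower_bound=lb, upper_bound=ub,
            subsystem=_coerce_subsystem(row.subsystem),
            gpr=parse_gpr(row.gpr)))
    if objective_id is None:
        candidates = [rid for rid, r in model.reactions.items()
                      if "biomass" in rid.lower()
                      or r.subsystem == "biomass"]
        if candidates:
            objective_id = candidates[0]
    if objective_id is not None:
        model.set_objective(objective_id)
    return model


def write_reaction_table(model: MetabolicModel, path: str | Path) -> None:
    rows = []
    for rid, rxn in model.reactions.items():
        rows.append({
            "reaction_id": rid,
            "name": rxn.name,
            "reaction": format_reaction_string(rxn),
            "gpr": rxn.gpr.to_string(),
            "subsystem": rxn.subsystem,
            "lower_bound": rxn.lower_bound,
            "upper_bound": rxn.upper_bound,
        })
    pd.DataFrame(rows, columns=TABLE_COLUMNS).to_csv(path, sep="\t",
                                                     index=False)


# ---------------------------------------------------------------------
# SBML level 2 version 1
# ---------------------------------------------------------------------

def _sbml_id(prefix: str, native_id: str) -> str:
    return prefix + re.sub(r"[^A-Za-z0-9_]", "_", native_id.replace("[", "_")
                           .replace("]", ""))


def _native_met_id(sid: str) -> str:
    body = sid[2:] if sid.startswith("M_") else sid
    for comp in ("c", "e"):
        if body.endswith(f"_{comp}"):
            return f"{body[:-2]}[{comp}]"
    return f"{body}[c]"


_NOTE_LINE = re.compile(r"([A-Z_]+):\s*(.*?)\s*$")


def _parse_notes(notes_xml: str) -> Dict[str, str]:
    out: Dict[str, str] = {}
    text = re.sub(r"<[^>]+>", "\n", notes_xml or "")
    for line in text.splitlines():
        m = _NOTE_LINE.match(line.strip())
        if m:
            out[m.group(1)] = m.group(2)
    return out


def _formula_string(formula: Dict[str, int]) -> str:
    return " ".join(f"{e}:{n}" for e, n in sorted(formula.items()))


def _parse_formula_string(text: str) -> Dict[str, int]:
    out: Dict[str, int] = {}
    for part in text.split():
        elem, n = part.split(":")
        out[elem] = int(n)
    return out


def write_sbml(model: MetabolicModel, path: str | Path) -> None:
    """Serialize to an SBML L2v1 document (pre-fbc COBRA dialect)."""
    import libsbml

    doc = libsbml.SBMLDocument(2, 1)
    sm = doc.createModel()
    sm.setId(_sbml_id("", model.id) or "model")
    for comp in ("c", "e"):
        c = sm.createCompartment()
        c.setId(comp)
        c.setSize(1.0)
    for met in model.metabolites.values():
        sp = sm.createSpecies()
        sp.setId(_sbml_id("M_", met.id))
        sp.setName(met.name or met.id)
        sp.setCompartment(met.compartment)
        sp.setInitialAmount(0.0)
        sp.setBoundaryCondition(False)
        if met.formula is not None:
            sp.setNotes(
                "<body xmlns='http://www.w3.org/1999/xhtml'>"
                f"<p>FORMULA: {_formula_string(met.formula)}</p></body>")
    for rid, rxn in model.reactions.items():
        sr = sm.createReaction()
        sr.setId(_sbml_id("R_", rid))
        sr.setName(rxn.name or rid)
        sr.setReversible(rxn.reversible)
        for mid, coeff in rxn.stoichiometry.items():
            ref = sr.createReactant() if coeff < 0 else sr.createProduct()
            ref.setSpecies(_sbml_id("M_", mid))
            ref.setStoichiometry(abs(coeff))
        notes = [f"GENE_ASSOCIATION: {rxn.gpr.to_string()}",
                 f"SUBSYSTEM: {rxn.subsystem}"]
        sr.setNotes("<body xmlns='http://www.w3.org/1999/xhtml'>"
                    + "".join(f"<p>{line}</p>" for line in notes) + "</body>")
        kl = sr.createKineticLaw()
        kl.setFormula("FLUX_VALUE")
        for pname, value in (("LOWER_BOUND", rxn.lower_bound),
                             ("UPPER_BOUND", rxn.upper_bound),
                             ("FLUX_VALUE", 0.0),
                             ("OBJECTIVE_COEFFICIENT",
                              model.objective.get(rid, 0.0))):
            p = kl.createParameter()
            p.setId(pname)
            p.setValue(float(value))
    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"could not write SBML to {path}")


def read_sbml(path: str | Path,
              objective_id: Optional[str] = None) -> "SbmlReadResult":
    """Read an SBML L2v1 model.

    Returns the model plus a count of reactions whose notes carried no
    GENE_ASSOCIATION line (tolerated: they get empty GPRs).  Bounds come
    from kinetic-law parameters when present, else default by the
    ``reversible`` attribute.  The objective is taken from
    OBJECTIVE_COEFFICIENT parameters, falling back to a reaction whose
    id or name contains "biomass".
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getModel() is None:
        raise SbmlDialectError(f"{path}: not a parseable SBML document")
    if (doc.getLevel(), doc.getVersion()) != (2, 1):
        raise SbmlDialectError(
            f"{path}: expected SBML level 2 version 1, got level "
            f"{doc.getLevel()} version {doc.getVersion()}")
    sm = doc.getModel()
    model = MetabolicModel(sm.getId() or Path(path).stem)
    sid_to_native: Dict[str, str] = {}
    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        native = _native_met_id(sp.getId())
        sid_to_native[sp.getId()] = native
        formula = None
        notes = _parse_notes(sp.getNotesString() if sp.isSetNotes() else "")
        if "FORMULA" in notes and notes["FORMULA"]:
            formula = _parse_formula_string(notes["FORMULA"])
        model.add_metabolite(Metabolite(native, sp.getName() or native,
                                        formula))
    missing_gpr = 0
    objective: Dict[str, float] = {}
    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        rid = sr.getId()
        if rid.startswith("R_"):
            rid = rid[2:]
        stoich: Dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            mid = sid_to_native[ref.getSpecies()]
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            mid = sid_to_native[ref.getSpecies()]
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        lb = -DEFAULT_BOUND if sr.getReversible() else 0.0
        ub = DEFAULT_BOUND
        obj_coeff = 0.0
        if sr.isSetKineticLaw():
            kl = sr.getKineticLaw()
            for k in range(kl.getNumParameters()):
                p = kl.getParameter(k)
                if p.getId() == "LOWER_BOUND":
                    lb = p.getValue()
                elif p.getId() == "UPPER_BOUND":
                    ub = p.getValue()
                elif p.getId() == "OBJECTIVE_COEFFICIENT":
                    obj_coeff = p.getValue()
        notes = _parse_notes(sr.getNotesString() if sr.isSetNotes() else "")
        gpr_text = notes.get("GENE_ASSOCIATION", "")
        if "GENE_ASSOCIATION" not in notes:
            missing_gpr += 1
        subsystem = _coerce_subsystem(notes.get("SUBSYSTEM", ""))
        model.add_reaction(Reaction(
            id=rid, stoichiometry=stoich, name=sr.getName() or rid,
            lower_bound=lb, upper_bound=ub, subsystem=subsystem,
            gpr=parse_gpr(gpr_text)))
        if obj_coeff:
            objective[rid] = obj_coeff
    if objective_id is not None:
        model.set_objective(objective_id)
    elif objective:
        model.objective = objective
    else:
        candidates = [rid for rid in model.reactions
                      if "biomass" in rid.lower()
                      or "biomass" in model.reactions[rid].name.lower()]
        if candidates:
            model.set_objective(candidates[0])
    return SbmlReadResult(model, missing_gpr)


@dataclass
class SbmlReadResult:
    model: MetabolicModel
    missing_gpr_count: int

    def __iter__(self):
        return iter((self.model, self.missing_gpr_count))
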