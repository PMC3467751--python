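"""SBML Level 3 Version 1 core + qual document model, writer and validator.

The output of the converter is one joint document per input pathway file: a
core model (compartments, species, reactions) readable by any SBML tool, plus
a qualitative model (qualitativeSpecies, transitions with signed inputs)
carrying the relations that are not stoichiometric reactions.  The writer is
byte-deterministic, orders elements per the SBML schema, never serializes an
empty ``listOf``, and renders CV terms as RDF/XML MIRIAM annotation blocks.

``validate_structure`` / ``validate_sbml_file`` implement the structural
validity rules the converter guarantees: declared-before-referenced species,
no duplicate identifiers, no dangling references, no empty lists, correct
element order, and well-formed input signs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Optional, Sequence

from lxml import etree

from .annotate import CvTerm, Qualifier
from .tables import Sign

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
QUAL_NS = "http://www.sbml.org/sbml/level3/version1/qual/version1"
RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
BQBIOL_NS = "http://biomodels.net/biology-qualifiers/"
XHTML_NS = "http://www.w3.org/1999/xhtml"

_QUALIFIER_ELEMENT = {
    Qualifier.IS: "is",
    Qualifier.IS_DESCRIBED_BY: "isDescribedBy",
    Qualifier.OCCURS_IN: "occursIn",
    Qualifier.HAS_PART: "hasPart",
}

SID_PATTERN = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")

#: Reaction SBO accessions that legitimise an empty reactant or product side.
DEGRADATION_SBO = 179
SYNTHESIS_SBO = 183


@dataclass
class Species:
    id: str
    name: str = ""
    compartment: str = "default"
    sbo_term: Optional[int] = None
    cv_terms: list[CvTerm] = field(default_factory=list)


@dataclass
class Reaction:
    id: str
    name: str = ""
    reversible: bool = False
    #: (species id, stoichiometric coefficient > 0)
    reactants: list[tuple[str, Fraction]] = field(default_factory=list)
    products: list[tuple[str, Fraction]] = field(default_factory=list)
    modifiers: list[str] = field(default_factory=list)
    sbo_term: Optional[int] = None


@dataclass
class QualitativeSpecies:
    id: str
    name: str = ""
    compartment: str = "default"
    sbo_term: Optional[int] = None
    cv_terms: list[CvTerm] = field(default_factory=list)


@dataclass
class Transition:
    id: str
    #: (qualitativeSpecies id, input sign)
    inputs: list[tuple[str, Sign]] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    sbo_term: Optional[int] = None


@dataclass
class SbmlDocument:
    """Joint core + qual model."""

    model_id: str = "model"
    model_name: str = ""
    organism_urn: Optional[str] = None
    compartments: list[tuple[str, str]] = field(default_factory=list)
    species: list[Species] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    qual_species: list[QualitativeSpecies] = field(default_factory=list)
    transitions: list[Transition] = field(default_factory=list)
    #: free-text provenance (tool, version, source file) for the model notes
    provenance: str = ""

    def all_ids(self) -> list[str]:
        ids = [self.model_id]
        ids += [cid for cid, _ in self.compartments]
        ids += [s.id for s in self.species]
        ids += [r.id for r in self.reactions]
        ids += [q.id for q in self.qual_species]
        ids += [t.id for t in self.transitions]
        return ids


# ---------------------------------------------------------------------------
# identifier sanitization


def sanitize_id(raw: str, taken: Optional[set[str]] = None) -> str:
    """Derive a valid SBML SId from a raw URI or name.

    Takes the fragment after ``#`` (or the last path segment), rewrites
    characters outside ``[A-Za-z0-9_]`` to underscores, prefixes an
    underscore when the result starts with a digit, and resolves collisions
    against ``taken`` with ``_2``, ``_3``, ... suffixes.  Deterministic.
    """
    if not raw:
        raise ValueError("cannot sanitize an empty identifier")
    frag = raw.rsplit("#", 1)[-1] if "#" in raw else raw
    if "/" in frag:
        frag = frag.rstrip("/").rsplit("/", 1)[-1]
    cand = re.sub(r"[^A-Za-z0-9_]", "_", frag)
    if not cand or cand[0].isdigit():
        cand = "_" + cand
    if taken is not None and cand in taken:
        n = 2
        while f"{cand}_{n}" in taken:
            n += 1
        cand = f"{cand}_{n}"
    return cand


# ---------------------------------------------------------------------------
# writer


def _fmt_stoich(value: Fraction) -> str:
    as_float = float(value)
    if as_float == int(as_float):
        return str(int(as_float))
    return repr(as_float)


def _sbo_attr(accession: int) -> str:
    return f"SBO:{accession:07d}"


def urn_to_url(urn: str) -> str:
    """Rewrite a MIRIAM URN to its identifiers.org URL form."""
    prefix = "urn:miriam:"
    if not urn.startswith(prefix):
        return urn
    collection, _, ident = urn[len(prefix):].partition(":")
    from urllib.parse import unquote

    return f"http://identifiers.org/{collection}/{unquote(ident)}"


def _append_cv_annotation(parent: etree._Element, meta_id: str,
                          terms: Sequence[CvTerm],
                          urn_style: str = "urn") -> None:
    if not terms:
        return
    parent.set("metaid", meta_id)
    annotation = etree.SubElement(parent, f"{{{SBML_NS}}}annotation")
    rdf = etree.SubElement(
        annotation, f"{{{RDF_NS}}}RDF",
        nsmap={"rdf": RDF_NS, "bqbiol": BQBIOL_NS},
    )
    desc = etree.SubElement(rdf, f"{{{RDF_NS}}}Description")
    desc.set(f"{{{RDF_NS}}}about", f"#{meta_id}")
    for term in terms:
        qual_el = etree.SubElement(
            desc, f"{{{BQBIOL_NS}}}{_QUALIFIER_ELEMENT[term.qualifier]}"
        )
        bag = etree.SubElement(qual_el, f"{{{RDF_NS}}}Bag")
        for urn in term.urns:
            li = etree.SubElement(bag, f"{{{RDF_NS}}}li")
            li.set(f"{{{RDF_NS}}}resource",
                   urn_to_url(urn) if urn_style == "url" else urn)


def sbml_to_bytes(doc: SbmlDocument, urn_style: str = "urn") -> bytes:
    """Serialize to SBML L3V1 XML with the qual package; byte-deterministic."""
    nsmap = {None: SBML_NS, "qual": QUAL_NS}
    root = etree.Element(f"{{{SBML_NS}}}sbml", nsmap=nsmap)
    root.set("level", "3")
    root.set("version", "1")
    root.set(f"{{{QUAL_NS}}}required", "false")

    model = etree.SubElement(root, f"{{{SBML_NS}}}model")
    model.set("id", doc.model_id)
    if doc.model_name:
        model.set("name", doc.model_name)

    if doc.provenance:
        notes = etree.SubElement(model, f"{{{SBML_NS}}}notes")
        body = etree.SubElement(notes, f"{{{XHTML_NS}}}body",
                                nsmap={None: XHTML_NS})
        for line in doc.provenance.splitlines():
            p = etree.SubElement(body, f"{{{XHTML_NS}}}p")
            p.text = line
    if doc.organism_urn:
        _append_cv_annotation(
            model, f"meta_{doc.model_id}",
            [CvTerm(Qualifier.OCCURS_IN, (doc.organism_urn,))],
            urn_style,
        )

    if doc.compartments:
        lst = etree.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
        for cid, cname in doc.compartments:
            comp = etree.SubElement(lst, f"{{{SBML_NS}}}compartment")
            comp.set("id", cid)
            if cname:
                comp.set("name", cname)
            comp.set("constant", "true")

    if doc.species:
        lst = etree.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
        for sp in doc.species:
            el = etree.SubElement(lst, f"{{{SBML_NS}}}species")
            el.set("id", sp.id)
            if sp.name:
                el.set("name", sp.name)
            el.set("compartment", sp.compartment)
            el.set("hasOnlySubstanceUnits", "false")
            el.set("boundaryCondition", "false")
            el.set("constant", "false")
            if sp.sbo_term is not None:
                el.set("sboTerm", _sbo_attr(sp.sbo_term))
            _append_cv_annotation(el, f"meta_{sp.id}", sp.cv_terms, urn_style)

    if doc.reactions:
        lst = etree.SubElement(model, f"{{{SBML_NS}}}listOfReactions")
        for rx in doc.reactions:
            el = etree.SubElement(lst, f"{{{SBML_NS}}}reaction")
            el.set("id", rx.id)
            if rx.name:
                el.set("name", rx.name)
            el.set("reversible", "true" if rx.reversible else "false")
            el.set("fast", "false")
            if rx.sbo_term is not None:
                el.set("sboTerm", _sbo_attr(rx.sbo_term))
            for tag, side in (("listOfReactants", rx.reactants),
                              ("listOfProducts", rx.products)):
                if not side:
                    continue
                side_el = etree.SubElement(el, f"{{{SBML_NS}}}{tag}")
                for sid, stoich in side:
                    ref = etree.SubElement(side_el,
                                           f"{{{SBML_NS}}}speciesReference")
                    ref.set("species", sid)
                    ref.set("stoichiometry", _fmt_stoich(stoich))
                    ref.set("constant", "true")
            if rx.modifiers:
                mods = etree.SubElement(el, f"{{{SBML_NS}}}listOfModifiers")
                for sid in rx.modifiers:
                    ref = etree.SubElement(
                        mods, f"{{{SBML_NS}}}modifierSpeciesReference")
                    ref.set("species", sid)

    if doc.qual_species:
        lst = etree.SubElement(model,
                               f"{{{QUAL_NS}}}listOfQualitativeSpecies")
        for qs in doc.qual_species:
            el = etree.SubElement(lst, f"{{{QUAL_NS}}}qualitativeSpecies")
            el.set(f"{{{QUAL_NS}}}id", qs.id)
            if qs.name:
                el.set(f"{{{QUAL_NS}}}name", qs.name)
            el.set(f"{{{QUAL_NS}}}compartment", qs.compartment)
            el.set(f"{{{QUAL_NS}}}constant", "false")
            if qs.sbo_term is not None:
                el.set("sboTerm", _sbo_attr(qs.sbo_term))
            _append_cv_annotation(el, f"meta_{qs.id}", qs.cv_terms, urn_style)

    if doc.transitions:
        lst = etree.SubElement(model, f"{{{QUAL_NS}}}listOfTransitions")
        for tr in doc.transitions:
            el = etree.SubElement(lst, f"{{{QUAL_NS}}}transition")
            el.set(f"{{{QUAL_NS}}}id", tr.id)
            if tr.sbo_term is not None:
                el.set("sboTerm", _sbo_attr(tr.sbo_term))
            if tr.inputs:
                in_lst = etree.SubElement(el, f"{{{QUAL_NS}}}listOfInputs")
                for i, (qsid, sign) in enumerate(tr.inputs):
                    inp = etree.SubElement(in_lst, f"{{{QUAL_NS}}}input")
                    inp.set(f"{{{QUAL_NS}}}id", f"{tr.id}_in_{i}")
                    inp.set(f"{{{QUAL_NS}}}qualitativeSpecies", qsid)
                    inp.set(f"{{{QUAL_NS}}}transitionEffect", "none")
                    inp.set(f"{{{QUAL_NS}}}sign", sign.value)
            out_lst = etree.SubElement(el, f"{{{QUAL_NS}}}listOfOutputs")
            for qsid in tr.outputs:
                out = etree.SubElement(out_lst, f"{{{QUAL_NS}}}output")
                out.set(f"{{{QUAL_NS}}}qualitativeSpecies", qsid)
                out.set(f"{{{QUAL_NS}}}transitionEffect", "assignmentLevel")

    return etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)


def write_sbml(doc: SbmlDocument, path: str | Path,
               urn_style: str = "urn") -> Path:
    report = validate_structure(doc)
    if report.issues:
        raise ValueError(f"refusing to write invalid document: {report}")
    path = Path(path)
    path.write_bytes(sbml_to_bytes(doc, urn_style))
    return path


# ---------------------------------------------------------------------------
# structural validation


@dataclass(frozen=True)
class Issue:
    code: str
    message: str

    def __str__(self) -> str:
        return f"{self.code}: {self.message}"


@dataclass
class ValidationReport:
    issues: list[Issue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def add(self, code: str, message: str) -> None:
        self.issues.append(Issue(code, message))

    def __str__(self) -> str:
        if self.ok:
            return "no structural issues"
        return "\n".join(str(i) for i in self.issues)


_SIGN_VALUES = {s.value for s in Sign}


def validate_structure(doc: SbmlDocument) -> ValidationReport:
    """Check a document against the converter's structural guarantees.

    Codes: ``DUPLICATE_ID`` (identifier reuse), ``MISSING_SPECIES`` (a
    reaction references an undeclared species), ``DANGLING_REF`` (unknown
    compartment or qualitativeSpecies reference), ``EMPTY_LISTOF`` (a
    reaction or transition with no participants where the SBO term does not
    justify it), ``BAD_SIGN`` (input sign outside the qual vocabulary).
    """
    report = ValidationReport()

    seen: set[str] = set()
    for sid in doc.all_ids():
        if sid in seen:
            report.add("DUPLICATE_ID", f"id {sid!r} declared more than once")
        seen.add(sid)
        if not SID_PATTERN.match(sid):
            report.add("DANGLING_REF", f"id {sid!r} violates SId grammar")

    compartment_ids = {cid for cid, _ in doc.compartments}
    species_ids = {s.id for s in doc.species}
    qual_ids = {q.id for q in doc.qual_species}

    for sp in doc.species:
        if sp.compartment not in compartment_ids:
            report.add("DANGLING_REF",
                       f"species {sp.id}: unknown compartment {sp.compartment!r}")
    for qs in doc.qual_species:
        if qs.compartment not in compartment_ids:
            report.add("DANGLING_REF",
                       f"qualitativeSpecies {qs.id}: unknown compartment "
                       f"{qs.compartment!r}")

    for rx in doc.reactions:
        for sid, _ in [*rx.reactants, *rx.products]:
            if sid not in species_ids:
                report.add("MISSING_SPECIES",
                           f"reaction {rx.id} references undeclared species {sid!r}")
        for sid in rx.modifiers:
            if sid not in species_ids:
                report.add("MISSING_SPECIES",
                           f"reaction {rx.id} modifier references undeclared "
                           f"species {sid!r}")
        if not rx.reactants and not rx.products:
            if rx.sbo_term not in (DEGRADATION_SBO, SYNTHESIS_SBO):
                report.add("EMPTY_LISTOF",
                           f"reaction {rx.id} has neither reactants nor products")

    for tr in doc.transitions:
        if not tr.outputs:
            report.add("EMPTY_LISTOF", f"transition {tr.id} has no outputs")
        for qsid, sign in tr.inputs:
            if qsid not in qual_ids:
                report.add("DANGLING_REF",
                           f"transition {tr.id} input references unknown "
                           f"qualitativeSpecies {qsid!r}")
            if sign.value not in _SIGN_VALUES:
                report.add("BAD_SIGN",
                           f"transition {tr.id}: bad sign {sign!r}")
        for qsid in tr.outputs:
            if qsid not in qual_ids:
                report.add("DANGLING_REF",
                           f"transition {tr.id} output references unknown "
                           f"qualitativeSpecies {qsid!r}")

    return report


_MODEL_CHILD_ORDER = [
    f"{{{SBML_NS}}}notes",
    f"{{{SBML_NS}}}annotation",
    f"{{{SBML_NS}}}listOfCompartments",
    f"{{{SBML_NS}}}listOfSpecies",
    f"{{{SBML_NS}}}listOfReactions",
    f"{{{QUAL_NS}}}listOfQualitativeSpecies",
    f"{{{QUAL_NS}}}listOfTransitions",
]


def validate_sbml_file(path: str | Path) -> ValidationReport:
    """Validate a serialized SBML file at the XML level.

    Besides re-checking duplicate ids, species references and input signs on
    the raw XML, this catches the two serialization-only defects:
    ``EMPTY_LISTOF`` (a listOf element with no children) and ``BAD_ORDER``
    (model children out of schema order).
    """
    report = ValidationReport()
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        report.add("BAD_ORDER", f"unreadable XML: {exc}")
        return report
    root = tree.getroot()

    ids: list[str] = []
    for el in root.iter():
        for attr in ("id", f"{{{QUAL_NS}}}id"):
            value = el.get(attr)
            if value is not None and not etree.QName(el).localname == "input":
                ids.append(value)
    dupes = {i for i in ids if ids.count(i) > 1}
    for dup in sorted(dupes):
        report.add("DUPLICATE_ID", f"id {dup!r} declared more than once")

    declared_species = {
        el.get("id") for el in root.iter(f"{{{SBML_NS}}}species")
    }
    for el in root.iter(f"{{{SBML_NS}}}speciesReference",
                        f"{{{SBML_NS}}}modifierSpeciesReference"):
        ref = el.get("species")
        if ref not in declared_species:
            report.add("MISSING_SPECIES",
                       f"reference to undeclared species {ref!r}")

    declared_qual = {
        el.get(f"{{{QUAL_NS}}}id")
        for el in root.iter(f"{{{QUAL_NS}}}qualitativeSpecies")
    }
    for el in root.iter(f"{{{QUAL_NS}}}input", f"{{{QUAL_NS}}}output"):
        ref = el.get(f"{{{QUAL_NS}}}qualitativeSpecies")
        if ref not in declared_qual:
            report.add("DANGLING_REF",
                       f"qual reference to unknown qualitativeSpecies {ref!r}")
    for el in root.iter(f"{{{QUAL_NS}}}input"):
        sign = el.get(f"{{{QUAL_NS}}}sign")
        if sign is not None and sign not in _SIGN_VALUES:
            report.add("BAD_SIGN", f"bad input sign {sign!r}")

    for el in root.iter():
        if etree.QName(el).localname.startswith("listOf") and len(el) == 0:
            report.add("EMPTY_LISTOF",
                       f"empty {etree.QName(el).localname} element")

    model = root.find(f"{{{SBML_NS}}}model")
    if model is not None:
        positions = [
            _MODEL_CHILD_ORDER.index(child.tag)
            for child in model
            if child.tag in _MODEL_CHILD_ORDER
        ]
        if positions != sorted(positions):
            report.add("BAD_ORDER", "model children out of schema order")

    return report
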