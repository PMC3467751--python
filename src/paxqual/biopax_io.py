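"""Reading and writing BioPAX OWL (RDF/XML) documents.

Reading goes through rdflib, which handles the RDF/XML details (rdf:ID versus
rdf:about, nested versus referenced resources, base resolution).  The two
BioPAX levels use different vocabularies — Level 2 lower-camel-case class
names and UPPER-CASE hyphenated properties with participant wrapper objects,
Level 3 capitalised class names and camelCase properties — so both dialects
are normalized into the shared :mod:`paxqual.model` representation through
per-level alias tables.  The level itself is detected from the BioPAX
namespace URI declared in the document.

Writing emits RDF/XML through lxml with explicit element ordering, so two
writes of the same document are byte-identical; rdflib's own serializer does
not guarantee that.  The writer emits the native dialect of the document's
level (including Level-2 participant wrappers) and round-trips with the
reader on the modeled subset.
"""

from __future__ import annotations

import logging
from fractions import Fraction
from pathlib import Path
from typing import Optional

from lxml import etree
from rdflib import Graph, RDF, URIRef

from .model import (
    BioPaxDocument,
    BioPaxEntity,
    BioPaxInteraction,
    BioPaxPathway,
    BioSource,
    EntityClass,
    InteractionKind,
    Participant,
    Xref,
)

logger = logging.getLogger(__name__)

BP3_NS = "http://www.biopax.org/release/biopax-level3.owl#"
BP2_NS = "http://www.biopax.org/release/biopax-level2.owl#"
RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
OWL_NS = "http://www.w3.org/2002/07/owl#"

#: Base used to resolve relative rdf:ID references deterministically.
DEFAULT_BASE = "http://paxqual.org/document"


class BioPaxIOError(Exception):
    pass


class MalformedXmlError(BioPaxIOError):
    pass


class UnknownNamespaceError(BioPaxIOError):
    pass


# --- class-name dialect tables ---------------------------------------------

_ENTITY_CLASSES = {
    # Level 3
    "Protein": EntityClass.PROTEIN,
    "Complex": EntityClass.COMPLEX,
    "Dna": EntityClass.DNA,
    "DnaRegion": EntityClass.DNA_REGION,
    "Rna": EntityClass.RNA,
    "RnaRegion": EntityClass.RNA_REGION,
    "SmallMolecule": EntityClass.SMALL_MOLECULE,
    "Gene": EntityClass.GENE,
    "PhysicalEntity": EntityClass.GENERIC,
    "SimplePhysicalEntity": EntityClass.GENERIC,
    # Level 2
    "protein": EntityClass.PROTEIN,
    "complex": EntityClass.COMPLEX,
    "dna": EntityClass.DNA,
    "rna": EntityClass.RNA,
    "smallMolecule": EntityClass.SMALL_MOLECULE,
    "physicalEntity": EntityClass.GENERIC,
}

_INTERACTION_KINDS = {
    # Level 3
    "BiochemicalReaction": InteractionKind.BIOCHEMICAL_REACTION,
    "ComplexAssembly": InteractionKind.COMPLEX_ASSEMBLY,
    "Transport": InteractionKind.TRANSPORT,
    "TransportWithBiochemicalReaction":
        InteractionKind.TRANSPORT_WITH_BIOCHEMICAL_REACTION,
    "Degradation": InteractionKind.DEGRADATION,
    "Conversion": InteractionKind.GENERIC_CONVERSION,
    "Control": InteractionKind.CONTROL,
    "Catalysis": InteractionKind.CATALYSIS,
    "Modulation": InteractionKind.MODULATION,
    "TemplateReactionRegulation":
        InteractionKind.TEMPLATE_REACTION_REGULATION,
    "TemplateReaction": InteractionKind.TEMPLATE_REACTION,
    "Interaction": InteractionKind.GENERIC_INTERACTION,
    # Level 2
    "biochemicalReaction": InteractionKind.BIOCHEMICAL_REACTION,
    "complexAssembly": InteractionKind.COMPLEX_ASSEMBLY,
    "transport": InteractionKind.TRANSPORT,
    "transportWithBiochemicalReaction":
        InteractionKind.TRANSPORT_WITH_BIOCHEMICAL_REACTION,
    "conversion": InteractionKind.GENERIC_CONVERSION,
    "control": InteractionKind.CONTROL,
    "catalysis": InteractionKind.CATALYSIS,
    "modulation": InteractionKind.MODULATION,
    "interaction": InteractionKind.GENERIC_INTERACTION,
}

#: Rare interaction classes folded into the generic interaction with a warning.
_RARE_INTERACTIONS = {
    "MolecularInteraction", "GeneticInteraction", "physicalInteraction",
}

_PATHWAY_CLASSES = {"Pathway", "pathway"}
_BIOSOURCE_CLASSES = {"BioSource", "bioSource"}
#: Helper classes the reader dereferences through but never instantiates.
_HELPER_CLASSES = {
    "UnificationXref", "RelationshipXref", "PublicationXref", "Xref",
    "unificationXref", "relationshipXref", "publicationXref", "xref",
    "CellularLocationVocabulary", "ControlledVocabulary",
    "openControlledVocabulary",
    "Stoichiometry", "physicalEntityParticipant", "sequenceParticipant",
    "Provenance", "dataSource", "Evidence", "evidence", "pathwayStep",
    "PathwayStep", "BiochemicalPathwayStep",
}

# --- property aliases (Level 3 camelCase first, then Level 2) ---------------

_P_NAME = ("displayName", "standardName", "name", "NAME", "SHORT-NAME")
_P_LOCATION = ("cellularLocation", "CELLULAR-LOCATION")
_P_TERM = ("term", "TERM")
_P_XREF = ("xref", "XREF", "TAXON-XREF")
_P_DB = ("db", "DB")
_P_ID = ("id", "ID")
_P_COMPONENT = ("component", "COMPONENTS")
_P_LEFT = ("left", "LEFT", "template")
_P_RIGHT = ("right", "RIGHT", "product", "participant", "PARTICIPANTS")
_P_CONTROLLER = ("controller", "CONTROLLER")
_P_CONTROLLED = ("controlled", "CONTROLLED")
_P_CONTROL_TYPE = ("controlType", "CONTROL-TYPE")
_P_ORGANISM = ("organism", "ORGANISM")
_P_PATHWAY_COMPONENT = ("pathwayComponent", "PATHWAY-COMPONENTS")
_P_STOICH_OF = ("participantStoichiometry",)
_P_STOICH_ENTITY = ("physicalEntity", "PHYSICAL-ENTITY")
_P_STOICH_COEFF = ("stoichiometricCoefficient", "STOICHIOMETRIC-COEFFICIENT")


class _GraphView:
    """Thin convenience layer over the rdflib graph for one BioPAX namespace."""

    def __init__(self, graph: Graph, ns: str):
        self.graph = graph
        self.ns = ns

    def prop(self, name: str) -> URIRef:
        return URIRef(self.ns + name)

    def objects(self, subject: URIRef, aliases: tuple[str, ...]) -> list:
        out = []
        for alias in aliases:
            out.extend(self.graph.objects(subject, self.prop(alias)))
        return out

    def literal(self, subject: URIRef, aliases: tuple[str, ...]) -> Optional[str]:
        for obj in self.objects(subject, aliases):
            return str(obj)
        return None

    def type_localname(self, subject) -> Optional[str]:
        for t in self.graph.objects(subject, RDF.type):
            t = str(t)
            if t.startswith(self.ns):
                return t[len(self.ns):]
        return None


def _document_order(path: Path) -> dict[str, int]:
    """Rank URIs (by fragment / verbatim value) in XML document order."""
    ranks: dict[str, int] = {}
    try:
        for i, (_, el) in enumerate(etree.iterparse(str(path), events=("start",))):
            for attr in (f"{{{RDF_NS}}}ID", f"{{{RDF_NS}}}about"):
                value = el.get(attr)
                if value is not None:
                    key = value.rsplit("#", 1)[-1]
                    ranks.setdefault(key, i)
    except etree.XMLSyntaxError:
        pass
    return ranks


def read_biopax(path: str | Path) -> BioPaxDocument:
    """Parse a BioPAX Level 2 or Level 3 RDF/XML file.

    The level is detected from the BioPAX namespace; documents without a
    Pathway element parse fine.  Raises :class:`MalformedXmlError` for broken
    XML and :class:`UnknownNamespaceError` when neither BioPAX namespace is
    present.
    """
    path = Path(path)
    graph = Graph()
    try:
        graph.parse(str(path), format="xml", publicID=DEFAULT_BASE)
    except (etree.XMLSyntaxError, Exception) as exc:  # rdflib wraps sax errors
        if isinstance(exc, OSError):
            raise
        raise MalformedXmlError(f"{path}: {exc}") from exc

    all_text = " ".join(
        str(term) for triple in graph for term in triple
    )
    if BP3_NS[:-1] in all_text:
        level, ns = 3, BP3_NS
    elif BP2_NS[:-1] in all_text:
        level, ns = 2, BP2_NS
    else:
        raise UnknownNamespaceError(
            f"{path}: neither BioPAX Level 2 nor Level 3 namespace found"
        )
    view = _GraphView(graph, ns)

    order = _document_order(path)

    def rank(uri: str):
        return (order.get(str(uri).rsplit("#", 1)[-1], 1 << 30), str(uri))

    typed: list[tuple[URIRef, str]] = []
    for subject in sorted(set(graph.subjects(RDF.type, None)), key=rank):
        localname = view.type_localname(subject)
        if localname is not None:
            typed.append((subject, localname))

    def read_xrefs(subject) -> list[Xref]:
        xrefs = []
        for node in view.objects(subject, _P_XREF):
            db = view.literal(node, _P_DB)
            ident = view.literal(node, _P_ID)
            if db and ident:
                xrefs.append(Xref(db, ident))
        return xrefs

    def read_location(subject) -> Optional[str]:
        for node in view.objects(subject, _P_LOCATION):
            term = view.literal(node, _P_TERM)
            if term:
                return term
            text = str(node)
            if not text.startswith("http") and "#" not in text:
                return text  # plain literal location
        return None

    def unwrap(node) -> tuple[URIRef, Fraction, Optional[str]]:
        """Resolve a participant: unwrap Level-2 wrapper objects."""
        target = view.objects(node, _P_STOICH_ENTITY)
        if target:
            coeff = view.literal(node, _P_STOICH_COEFF)
            stoich = Fraction(coeff) if coeff else Fraction(1)
            return target[0], stoich, read_location(node)
        return node, Fraction(1), None

    entities: list[BioPaxEntity] = []
    interactions: list[BioPaxInteraction] = []
    pathways: list[BioPaxPathway] = []
    bio_sources: list[BioSource] = []

    for subject, localname in typed:
        uri = str(subject)
        if localname in _HELPER_CLASSES or localname == "Ontology":
            continue
        if localname in _ENTITY_CLASSES:
            components = []
            for node in view.objects(subject, _P_COMPONENT):
                ref, _, _ = unwrap(node)
                components.append(str(ref))
            entities.append(BioPaxEntity(
                uri=uri,
                entity_class=_ENTITY_CLASSES[localname],
                display_name=view.literal(subject, _P_NAME) or "",
                cellular_location=read_location(subject),
                xrefs=read_xrefs(subject),
                component_refs=sorted(components),
            ))
        elif localname in _INTERACTION_KINDS or localname in _RARE_INTERACTIONS:
            if localname in _RARE_INTERACTIONS:
                logger.warning("%s: rare class %s mapped to generic interaction",
                               uri, localname)
                kind = InteractionKind.GENERIC_INTERACTION
            else:
                kind = _INTERACTION_KINDS[localname]

            # Level-3 per-interaction stoichiometry assignments
            stoich_by_entity: dict[str, Fraction] = {}
            for node in view.objects(subject, _P_STOICH_OF):
                ent = view.objects(node, _P_STOICH_ENTITY)
                coeff = view.literal(node, _P_STOICH_COEFF)
                if ent and coeff:
                    stoich_by_entity[str(ent[0])] = Fraction(coeff)

            def read_side(aliases) -> list[Participant]:
                side = []
                for node in view.objects(subject, aliases):
                    ref, stoich, loc = unwrap(node)
                    ref = str(ref)
                    if stoich == 1 and ref in stoich_by_entity:
                        stoich = stoich_by_entity[ref]
                    side.append(Participant(ref, stoich, loc))
                return sorted(side, key=lambda p: (rank(p.ref), p.ref))

            controllers = []
            for node in view.objects(subject, _P_CONTROLLER):
                ref, _, _ = unwrap(node)
                controllers.append(str(ref))
            controlled_nodes = view.objects(subject, _P_CONTROLLED)

            interactions.append(BioPaxInteraction(
                uri=uri,
                kind=kind,
                display_name=view.literal(subject, _P_NAME) or "",
                left=read_side(_P_LEFT),
                right=read_side(_P_RIGHT),
                controllers=sorted(controllers),
                controlled=str(controlled_nodes[0]) if controlled_nodes else None,
                control_type=view.literal(subject, _P_CONTROL_TYPE),
            ))
        elif localname in _PATHWAY_CLASSES:
            refs = [str(n) for n in view.objects(subject, _P_PATHWAY_COMPONENT)]
            pathways.append(BioPaxPathway(
                uri=uri,
                display_name=view.literal(subject, _P_NAME) or "",
                component_interaction_refs=sorted(refs),
            ))
        elif localname in _BIOSOURCE_CLASSES:
            name = view.literal(subject, _P_NAME)
            tax = None
            for xref in read_xrefs(subject):
                tax = xref.id_value
                break
            if name or tax:
                bio_sources.append(BioSource(name=name, taxonomy_id=tax))
        else:
            logger.debug("%s: ignoring unmodeled class %s", uri, localname)

    return BioPaxDocument(
        level=level,
        entities=entities,
        interactions=interactions,
        pathways=pathways,
        bio_sources=bio_sources,
        source_uri=str(path),
    )


# ---------------------------------------------------------------------------
# writer


_L3_CLASS_OF_ENTITY = {
    EntityClass.PROTEIN: "Protein",
    EntityClass.COMPLEX: "Complex",
    EntityClass.DNA: "Dna",
    EntityClass.DNA_REGION: "DnaRegion",
    EntityClass.RNA: "Rna",
    EntityClass.RNA_REGION: "RnaRegion",
    EntityClass.SMALL_MOLECULE: "SmallMolecule",
    EntityClass.GENE: "Gene",
    EntityClass.GENERIC: "PhysicalEntity",
}
_L2_CLASS_OF_ENTITY = {
    EntityClass.PROTEIN: "protein",
    EntityClass.COMPLEX: "complex",
    EntityClass.DNA: "dna",
    EntityClass.RNA: "rna",
    EntityClass.SMALL_MOLECULE: "smallMolecule",
    EntityClass.GENERIC: "physicalEntity",
}
_L3_CLASS_OF_KIND = {
    InteractionKind.BIOCHEMICAL_REACTION: "BiochemicalReaction",
    InteractionKind.COMPLEX_ASSEMBLY: "ComplexAssembly",
    InteractionKind.TRANSPORT: "Transport",
    InteractionKind.TRANSPORT_WITH_BIOCHEMICAL_REACTION:
        "TransportWithBiochemicalReaction",
    InteractionKind.DEGRADATION: "Degradation",
    InteractionKind.GENERIC_CONVERSION: "Conversion",
    InteractionKind.CONTROL: "Control",
    InteractionKind.CATALYSIS: "Catalysis",
    InteractionKind.MODULATION: "Modulation",
    InteractionKind.TEMPLATE_REACTION_REGULATION: "TemplateReactionRegulation",
    InteractionKind.TEMPLATE_REACTION: "TemplateReaction",
    InteractionKind.GENERIC_INTERACTION: "Interaction",
}
_L2_CLASS_OF_KIND = {
    InteractionKind.BIOCHEMICAL_REACTION: "biochemicalReaction",
    InteractionKind.COMPLEX_ASSEMBLY: "complexAssembly",
    InteractionKind.TRANSPORT: "transport",
    InteractionKind.TRANSPORT_WITH_BIOCHEMICAL_REACTION:
        "transportWithBiochemicalReaction",
    InteractionKind.GENERIC_CONVERSION: "conversion",
    InteractionKind.CONTROL: "control",
    InteractionKind.CATALYSIS: "catalysis",
    InteractionKind.MODULATION: "modulation",
    InteractionKind.GENERIC_INTERACTION: "interaction",
}


def _coeff_str(value: Fraction) -> str:
    return repr(float(value))


class _Writer:
    def __init__(self, doc: BioPaxDocument):
        self.doc = doc
        self.ns = BP3_NS if doc.level == 3 else BP2_NS
        self.nsmap = {"rdf": RDF_NS, "owl": OWL_NS, "bp": self.ns}
        self.root = etree.Element(f"{{{RDF_NS}}}RDF", nsmap=self.nsmap)
        ont = etree.SubElement(self.root, f"{{{OWL_NS}}}Ontology")
        ont.set(f"{{{RDF_NS}}}about", "")
        imports = etree.SubElement(ont, f"{{{OWL_NS}}}imports")
        imports.set(f"{{{RDF_NS}}}resource", self.ns.rstrip("#"))

    def el(self, parent, localname: str, about: Optional[str] = None,
           resource: Optional[str] = None, text: Optional[str] = None):
        node = etree.SubElement(parent, f"{{{self.ns}}}{localname}")
        if about is not None:
            node.set(f"{{{RDF_NS}}}about", about)
        if resource is not None:
            node.set(f"{{{RDF_NS}}}resource", resource)
        if text is not None:
            node.text = text
        return node

    def name_prop(self, parent, name: str) -> None:
        if name:
            tag = "displayName" if self.doc.level == 3 else "NAME"
            self.el(parent, tag, text=name)

    def location_prop(self, parent, owner_uri: str, location: str,
                      suffix: str = "_loc") -> None:
        tag = "cellularLocation" if self.doc.level == 3 else "CELLULAR-LOCATION"
        voc_class = ("CellularLocationVocabulary" if self.doc.level == 3
                     else "openControlledVocabulary")
        term_tag = "term" if self.doc.level == 3 else "TERM"
        prop = self.el(parent, tag)
        voc = self.el(prop, voc_class, about=f"{owner_uri}{suffix}")
        self.el(voc, term_tag, text=location)

    def xref_props(self, parent, owner_uri: str, xrefs: list[Xref],
                   tag: Optional[str] = None) -> None:
        tag = tag or ("xref" if self.doc.level == 3 else "XREF")
        xref_class = ("UnificationXref" if self.doc.level == 3
                      else "unificationXref")
        db_tag = "db" if self.doc.level == 3 else "DB"
        id_tag = "id" if self.doc.level == 3 else "ID"
        for i, xref in enumerate(xrefs):
            prop = self.el(parent, tag)
            node = self.el(prop, xref_class, about=f"{owner_uri}_xref{i}")
            self.el(node, db_tag, text=xref.db_raw)
            self.el(node, id_tag, text=xref.id_value)

    def entity_el(self, entity: BioPaxEntity):
        if self.doc.level == 3:
            cls = _L3_CLASS_OF_ENTITY[entity.entity_class]
        else:
            cls = _L2_CLASS_OF_ENTITY[entity.entity_class]
        node = self.el(self.root, cls, about=entity.uri)
        self.name_prop(node, entity.display_name)
        if entity.cellular_location:
            self.location_prop(node, entity.uri, entity.cellular_location)
        self.xref_props(node, entity.uri, entity.xrefs)
        comp_tag = "component" if self.doc.level == 3 else "COMPONENTS"
        for ref in entity.component_refs:
            if self.doc.level == 3:
                self.el(node, comp_tag, resource=ref)
            else:
                prop = self.el(node, comp_tag)
                wrapper = self.el(prop, "physicalEntityParticipant",
                                  about=f"{entity.uri}_comp_{_frag(ref)}")
                self.el(wrapper, "PHYSICAL-ENTITY", resource=ref)

    def side_props(self, node, ia: BioPaxInteraction, side: str) -> None:
        participants = ia.left if side == "left" else ia.right
        if self.doc.level == 3:
            if ia.kind is InteractionKind.TEMPLATE_REACTION:
                tag = "template" if side == "left" else "product"
            elif ia.kind is InteractionKind.GENERIC_INTERACTION:
                tag = "participant"
            else:
                tag = side
            for part in participants:
                self.el(node, tag, resource=part.ref)
            for i, part in enumerate(participants):
                if part.stoichiometry != 1:
                    prop = self.el(node, "participantStoichiometry")
                    st = self.el(prop, "Stoichiometry",
                                 about=f"{ia.uri}_stoich_{side}_{i}")
                    self.el(st, "physicalEntity", resource=part.ref)
                    self.el(st, "stoichiometricCoefficient",
                            text=_coeff_str(part.stoichiometry))
        else:
            if ia.kind is InteractionKind.GENERIC_INTERACTION:
                tag = "PARTICIPANTS"
            else:
                tag = side.upper()
            for i, part in enumerate(participants):
                prop = self.el(node, tag)
                wrapper = self.el(prop, "physicalEntityParticipant",
                                  about=f"{ia.uri}_{side}_{i}")
                self.el(wrapper, "PHYSICAL-ENTITY", resource=part.ref)
                if part.stoichiometry != 1:
                    self.el(wrapper, "STOICHIOMETRIC-COEFFICIENT",
                            text=_coeff_str(part.stoichiometry))
                if part.location:
                    self.location_prop(wrapper, f"{ia.uri}_{side}_{i}",
                                       part.location)

    def interaction_el(self, ia: BioPaxInteraction):
        if self.doc.level == 3:
            cls = _L3_CLASS_OF_KIND[ia.kind]
        else:
            cls = _L2_CLASS_OF_KIND[ia.kind]
        node = self.el(self.root, cls, about=ia.uri)
        self.name_prop(node, ia.display_name)
        self.side_props(node, ia, "left")
        self.side_props(node, ia, "right")
        ctl_tag = "controller" if self.doc.level == 3 else "CONTROLLER"
        for i, ref in enumerate(ia.controllers):
            if self.doc.level == 3 or self.doc.resolve(ref) in self.doc.pathways:
                self.el(node, ctl_tag, resource=ref)
            else:
                prop = self.el(node, ctl_tag)
                wrapper = self.el(prop, "physicalEntityParticipant",
                                  about=f"{ia.uri}_ctl_{i}")
                self.el(wrapper, "PHYSICAL-ENTITY", resource=ref)
        if ia.controlled is not None:
            tag = "controlled" if self.doc.level == 3 else "CONTROLLED"
            self.el(node, tag, resource=ia.controlled)
        if ia.control_type:
            tag = "controlType" if self.doc.level == 3 else "CONTROL-TYPE"
            self.el(node, tag, text=ia.control_type)

    def pathway_el(self, pw: BioPaxPathway, organism_uri: Optional[str]):
        cls = "Pathway" if self.doc.level == 3 else "pathway"
        node = self.el(self.root, cls, about=pw.uri)
        self.name_prop(node, pw.display_name)
        tag = ("pathwayComponent" if self.doc.level == 3
               else "PATHWAY-COMPONENTS")
        for ref in pw.component_interaction_refs:
            self.el(node, tag, resource=ref)
        if organism_uri is not None:
            tag = "organism" if self.doc.level == 3 else "ORGANISM"
            self.el(node, tag, resource=organism_uri)

    def biosource_el(self, source: BioSource, uri: str):
        cls = "BioSource" if self.doc.level == 3 else "bioSource"
        node = self.el(self.root, cls, about=uri)
        if source.name:
            self.name_prop(node, source.name)
        if source.taxonomy_id:
            tag = "xref" if self.doc.level == 3 else "TAXON-XREF"
            self.xref_props(node, uri, [Xref("Taxonomy", source.taxonomy_id)],
                            tag=tag)

    def build(self) -> bytes:
        doc = self.doc
        biosource_uris = [
            f"{DEFAULT_BASE}#biosource_{i}" for i in range(len(doc.bio_sources))
        ]
        for ent in doc.entities:
            self.entity_el(ent)
        for ia in doc.interactions:
            self.interaction_el(ia)
        for i, pw in enumerate(doc.pathways):
            organism = biosource_uris[0] if (i == 0 and biosource_uris) else None
            self.pathway_el(pw, organism)
        for uri, source in zip(biosource_uris, doc.bio_sources):
            self.biosource_el(source, uri)
        return etree.tostring(self.root, xml_declaration=True,
                              encoding="UTF-8", pretty_print=True)


def _frag(uri: str) -> str:
    return uri.rsplit("#", 1)[-1]


def biopax_to_bytes(doc: BioPaxDocument) -> bytes:
    """Serialize a document to BioPAX RDF/XML; byte-deterministic."""
    missing = doc.check_references()
    if missing:
        raise BioPaxIOError(f"document has unresolved references: {missing}")
    return _Writer(doc).build()


def write_biopax(doc: BioPaxDocument, path: str | Path) -> Path:
    path = Path(path)
    path.write_bytes(biopax_to_bytes(doc))
    return path
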