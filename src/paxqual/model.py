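"""In-memory representation of a BioPAX Level 2/3 pathway document.

BioPAX organises everything under a single ``Entity`` superclass, split into
physical entities (proteins, complexes, nucleic acids, small molecules, and in
Level 3 also genes and DNA/RNA regions) and interactions (conversions and
controls).  This module models exactly the subset of that ontology the
converter needs: entities with names, locations and cross-references;
interactions with participants, stoichiometries, controllers and control
types; pathways; and the organism (``BioSource``).

Level 2 and Level 3 documents share one representation.  Classes that only
exist in Level 3 (``Gene``, ``DnaRegion``, ``RnaRegion``) are rejected on a
level-2 document at construction time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from typing import Optional, Union

logger = logging.getLogger(__name__)


class BioPaxError(Exception):
    """Base class for BioPAX model errors."""


class UnresolvedReferenceError(BioPaxError, KeyError):
    """A URI referenced by an interaction does not resolve in the document."""

    def __init__(self, uri: str):
        super().__init__(uri)
        self.uri = uri

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return f"unresolved reference: {self.uri!r}"


class InvariantError(BioPaxError, ValueError):
    """A document or element violates a structural invariant."""


class EntityClass(str, Enum):
    """Physical-entity classes shared between BioPAX Levels 2 and 3.

    ``GENE``, ``DNA_REGION`` and ``RNA_REGION`` exist only in Level 3.
    ``GENERIC`` covers a plain (untyped) physicalEntity/PhysicalEntity.
    """

    GENE = "Gene"
    COMPLEX = "Complex"
    PROTEIN = "Protein"
    DNA = "DNA"
    DNA_REGION = "DnaRegion"
    RNA = "Rna"
    RNA_REGION = "RnaRegion"
    SMALL_MOLECULE = "SmallMolecule"
    GENERIC = "GenericPhysicalEntity"


#: Entity classes that only exist in BioPAX Level 3.
LEVEL3_ONLY_ENTITY_CLASSES = frozenset(
    {EntityClass.GENE, EntityClass.DNA_REGION, EntityClass.RNA_REGION}
)


class InteractionKind(str, Enum):
    """Interaction classes, conversions first, then controls."""

    BIOCHEMICAL_REACTION = "BiochemicalReaction"
    COMPLEX_ASSEMBLY = "ComplexAssembly"
    TRANSPORT = "Transport"
    TRANSPORT_WITH_BIOCHEMICAL_REACTION = "TransportWithBiochemicalReaction"
    DEGRADATION = "Degradation"
    GENERIC_CONVERSION = "GenericConversion"
    CONTROL = "Control"
    CATALYSIS = "Catalysis"
    MODULATION = "Modulation"
    TEMPLATE_REACTION_REGULATION = "TemplateReactionRegulation"
    TEMPLATE_REACTION = "TemplateReaction"
    GENERIC_INTERACTION = "GenericInteraction"


CONVERSION_KINDS = frozenset(
    {
        InteractionKind.BIOCHEMICAL_REACTION,
        InteractionKind.COMPLEX_ASSEMBLY,
        InteractionKind.TRANSPORT,
        InteractionKind.TRANSPORT_WITH_BIOCHEMICAL_REACTION,
        InteractionKind.DEGRADATION,
        InteractionKind.GENERIC_CONVERSION,
    }
)

CONTROL_KINDS = frozenset(
    {
        InteractionKind.CONTROL,
        InteractionKind.CATALYSIS,
        InteractionKind.MODULATION,
        InteractionKind.TEMPLATE_REACTION_REGULATION,
    }
)

#: Interaction kinds that only exist in BioPAX Level 3.
LEVEL3_ONLY_INTERACTION_KINDS = frozenset(
    {
        InteractionKind.DEGRADATION,
        InteractionKind.TEMPLATE_REACTION,
        InteractionKind.TEMPLATE_REACTION_REGULATION,
    }
)


@dataclass(frozen=True)
class Xref:
    """A cross-reference: a verbatim database name plus an identifier."""

    db_raw: str
    id_value: str

    def __post_init__(self) -> None:
        if not self.db_raw or not self.id_value:
            raise InvariantError("Xref requires non-empty db and id")


@dataclass(frozen=True)
class BioSource:
    """The organism a pathway belongs to (name and/or NCBI taxonomy id)."""

    name: Optional[str] = None
    taxonomy_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.name and not self.taxonomy_id:
            raise InvariantError("BioSource requires a name or a taxonomy id")


@dataclass
class BioPaxEntity:
    """A physical entity (or Level-3 Gene) participating in interactions."""

    uri: str
    entity_class: EntityClass
    display_name: str = ""
    cellular_location: Optional[str] = None
    xrefs: list[Xref] = field(default_factory=list)
    #: URIs of member entities; non-empty only for complexes.
    component_refs: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.component_refs and self.entity_class is not EntityClass.COMPLEX:
            raise InvariantError(
                f"{self.uri}: only Complex entities may have components"
            )


@dataclass(frozen=True)
class Participant:
    """One side-entry of a conversion: entity reference, coefficient, and an
    optional location override (Level-2 participant wrappers may place an
    entity in a different compartment than its default)."""

    ref: str
    stoichiometry: Fraction = Fraction(1)
    location: Optional[str] = None

    def __post_init__(self) -> None:
        if self.stoichiometry <= 0:
            raise InvariantError("stoichiometry must be positive")


@dataclass
class BioPaxInteraction:
    """A conversion (left/right participants) or a control (controller(s) and
    at most one controlled element)."""

    uri: str
    kind: InteractionKind
    display_name: str = ""
    left: list[Participant] = field(default_factory=list)
    right: list[Participant] = field(default_factory=list)
    controllers: list[str] = field(default_factory=list)
    controlled: Optional[str] = None
    control_type: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind in CONVERSION_KINDS and (self.controllers or self.controlled):
            raise InvariantError(
                f"{self.uri}: conversion interactions carry no controller/controlled"
            )

    @property
    def is_conversion(self) -> bool:
        return self.kind in CONVERSION_KINDS

    @property
    def is_control(self) -> bool:
        return self.kind in CONTROL_KINDS


@dataclass
class BioPaxPathway:
    """A pathway; may itself act as controller or controlled element."""

    uri: str
    display_name: str = ""
    component_interaction_refs: list[str] = field(default_factory=list)


BioPaxObject = Union[BioPaxEntity, BioPaxInteraction, BioPaxPathway]


@dataclass
class BioPaxDocument:
    """A parsed BioPAX document: entities, interactions, pathways, organism.

    ``level`` is 2 or 3; Level-3-only classes are rejected on a level-2
    document.  All URIs are unique document-wide, and every reference held by
    an interaction must resolve within the document (checked by
    :meth:`check_references`).
    """

    level: int
    entities: list[BioPaxEntity] = field(default_factory=list)
    interactions: list[BioPaxInteraction] = field(default_factory=list)
    pathways: list[BioPaxPathway] = field(default_factory=list)
    bio_sources: list[BioSource] = field(default_factory=list)
    source_uri: str = ""

    def __post_init__(self) -> None:
        if self.level not in (2, 3):
            raise InvariantError(f"BioPAX level must be 2 or 3, got {self.level}")
        if self.level == 2:
            for ent in self.entities:
                if ent.entity_class in LEVEL3_ONLY_ENTITY_CLASSES:
                    raise InvariantError(
                        f"{ent.uri}: {ent.entity_class.value} requires Level 3"
                    )
            for ia in self.interactions:
                if ia.kind in LEVEL3_ONLY_INTERACTION_KINDS:
                    raise InvariantError(
                        f"{ia.uri}: {ia.kind.value} requires Level 3"
                    )
        self._index: dict[str, BioPaxObject] = {}
        for obj in [*self.entities, *self.interactions, *self.pathways]:
            if obj.uri in self._index:
                raise InvariantError(f"duplicate URI in document: {obj.uri}")
            self._index[obj.uri] = obj

    def resolve(self, uri: str) -> BioPaxObject:
        """Return the entity, interaction or pathway with this URI.

        Raises :class:`UnresolvedReferenceError` when absent; the converter
        logs and skips the owning interaction in that case.
        """
        try:
            return self._index[uri]
        except KeyError:
            raise UnresolvedReferenceError(uri) from None

    def check_references(self) -> list[str]:
        """Exhaustively walk every reference; return the unresolved URIs."""
        missing: list[str] = []
        seen = set()

        def probe(uri: str) -> None:
            if uri in seen:
                return
            seen.add(uri)
            if uri not in self._index:
                missing.append(uri)

        for ent in self.entities:
            for ref in ent.component_refs:
                probe(ref)
        for ia in self.interactions:
            for part in [*ia.left, *ia.right]:
                probe(part.ref)
            for ref in ia.controllers:
                probe(ref)
            if ia.controlled is not None:
                probe(ia.controlled)
        for pw in self.pathways:
            for ref in pw.component_interaction_refs:
                probe(ref)
        return missing


def resolve_reference(doc: BioPaxDocument, uri: str) -> BioPaxObject:
    """Functional alias for :meth:`BioPaxDocument.resolve`."""
    return doc.resolve(uri)


class ParticipantKind(str, Enum):
    PHYSICAL_ENTITY = "physical_entity"
    PATHWAY = "pathway"
    INTERACTION = "interaction"


def participant_kind(doc: BioPaxDocument, ref: str) -> ParticipantKind:
    """Classify a controller/controlled reference.

    Controllers are physical entities or pathways; controlled elements are
    interactions or pathways.  This classification drives the
    reaction-versus-transition decision.
    """
    obj = doc.resolve(ref)
    if isinstance(obj, BioPaxEntity):
        return ParticipantKind.PHYSICAL_ENTITY
    if isinstance(obj, BioPaxPathway):
        return ParticipantKind.PATHWAY
    return ParticipantKind.INTERACTION
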