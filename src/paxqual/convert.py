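"""BioPAX → SBML core + qual conversion.

The translation runs in four steps:

1. **Initialize** the joint document: one SBML core model plus one
   qualitative model for the whole input file, annotated with the pathway
   organism (taxonomy URN) when a BioSource is present.
2. **Entities**: every physical entity becomes exactly one species *and* one
   qualitativeSpecies, SBO-termed by its class, placed in the compartment
   derived from its cellular location (or the default compartment).
3. **Interactions**: conversions (biochemical reactions, complex assemblies,
   transports, degradations) become stoichiometry-preserving core reactions.
   Controls become either a reaction *modifier* or a qual *transition*,
   decided by the (controller kind, controlled kind) pair per level; the
   control type determines the input sign (activation → positive,
   inhibition → negative, unspecified → unknown), and opposing controls on
   the same input/output pair merge to a dual sign.
4. **Annotation**: cross-references are normalized to MIRIAM URNs and
   augmented through the optional offline identifier-mapping table.

Conversion is a pure function of (document, config, tables): repeated runs
produce byte-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Optional, Union

from . import annotate as ann
from .model import (
    BioPaxDocument,
    BioPaxEntity,
    BioPaxInteraction,
    BioPaxPathway,
    CONTROL_KINDS,
    EntityClass,
    InteractionKind,
    ParticipantKind,
    UnresolvedReferenceError,
    participant_kind,
)
from .sbml import (
    QualitativeSpecies,
    Reaction,
    SbmlDocument,
    Species,
    Transition,
    sanitize_id,
)
from .tables import (
    MappingTables,
    PATHWAY_PROXY_SBO,
    REACTION_SBO,
    Sign,
    Translation,
    default_tables,
)

logger = logging.getLogger(__name__)

TOOL_NAME = "paxqual"
TOOL_VERSION = "1.0.0"


class ConversionError(Exception):
    pass


class UnmappedCombinationError(ConversionError, KeyError):
    """A (controller, controlled, level) triple outside the decision table."""


@dataclass
class ConversionConfig:
    default_compartment_id: str = "default"
    #: warn_skip: log and drop broken interactions; fail: raise.
    fallback_policy: str = "warn_skip"
    mapping_table_path: Optional[Path] = None
    deterministic_order: bool = True

    def __post_init__(self) -> None:
        from .sbml import SID_PATTERN

        if not SID_PATTERN.match(self.default_compartment_id):
            raise ValueError(
                f"invalid SBML id: {self.default_compartment_id!r}")
        if self.fallback_policy not in ("warn_skip", "fail"):
            raise ValueError(f"unknown policy {self.fallback_policy!r}")


def assign_sbo_term(entity_class: EntityClass, tables: MappingTables) -> int:
    """SBO accession for an entity class; the material-entity fallback for
    classes without a dedicated table row."""
    return tables.sbo_by_class.get(entity_class, tables.default_sbo)


def control_type_to_sign(control_type: Optional[str],
                         tables: Optional[MappingTables] = None) -> Sign:
    """Map a BioPAX controlType token to a qual input sign by prefix.

    ACTIVATION* → positive, INHIBITION* → negative, absent or unrecognized →
    unknown.  The dual sign is never produced here; it only arises when
    opposing controls merge.
    """
    if not control_type:
        return Sign.UNKNOWN
    tables = tables or default_tables()
    token = control_type.strip().upper()
    for prefix, sign in tables.sign_by_control_type.items():
        if token.startswith(prefix):
            return sign
    return Sign.UNKNOWN


_L2_TOKEN = {
    InteractionKind.BIOCHEMICAL_REACTION: "biochemicalReaction",
    InteractionKind.COMPLEX_ASSEMBLY: "complexAssembly",
    InteractionKind.TRANSPORT: "transport",
    InteractionKind.TRANSPORT_WITH_BIOCHEMICAL_REACTION:
        "transportWithBiochemicalReaction",
    InteractionKind.GENERIC_INTERACTION: "interaction",
    InteractionKind.GENERIC_CONVERSION: "interaction",
}
_L3_TOKEN = {
    InteractionKind.BIOCHEMICAL_REACTION: "BiochemicalReaction",
    InteractionKind.COMPLEX_ASSEMBLY: "ComplexAssembly",
    InteractionKind.TRANSPORT: "Transport",
    InteractionKind.TRANSPORT_WITH_BIOCHEMICAL_REACTION:
        "TransportWithBiochemicalReaction",
    InteractionKind.DEGRADATION: "Degradation",
    InteractionKind.GENERIC_CONVERSION: "Conversion",
    InteractionKind.TEMPLATE_REACTION: "TemplateReaction",
}

ControlledKind = Union[InteractionKind, str]


def _decision_token(controlled_kind: ControlledKind, level: int) -> Optional[str]:
    if isinstance(controlled_kind, str) and not isinstance(
            controlled_kind, InteractionKind):
        return controlled_kind  # literal table token, e.g. "pathway"
    table = _L3_TOKEN if level == 3 else _L2_TOKEN
    return table.get(controlled_kind)


def classify_control(controller_kind: Union[ParticipantKind, str],
                     controlled_kind: ControlledKind,
                     level: int,
                     tables: Optional[MappingTables] = None) -> Translation:
    """Decide reaction vs transition for one controller/controlled pair.

    ``controlled_kind`` may be an :class:`InteractionKind`, a literal
    decision-table token, or ``"pathway"``/``"Pathway"``.  Raises
    :class:`UnmappedCombinationError` for pairs outside the table.
    """
    tables = tables or default_tables()
    ctl = (controller_kind.value
           if isinstance(controller_kind, ParticipantKind) else controller_kind)
    token = _decision_token(controlled_kind, level)
    if token is not None:
        try:
            return tables.decision[(ctl, token, level)]
        except KeyError:
            pass
    raise UnmappedCombinationError(
        f"no decision-table row for ({ctl}, {controlled_kind}, level {level})"
    )


def init_models(doc: BioPaxDocument,
                config: Optional[ConversionConfig] = None) -> SbmlDocument:
    """Step 1: build the empty joint core + qual document.

    Both models cover the whole input file.  The first BioSource in document
    order supplies the organism (taxonomy URN); additional BioSources are
    ignored with a warning, and a missing one is only logged.
    """
    config = config or ConversionConfig()
    source = doc.source_uri or "in-memory document"
    model_id = sanitize_id(Path(source).stem or "model")
    out = SbmlDocument(
        model_id=model_id,
        provenance=(
            f"Converted by {TOOL_NAME} {TOOL_VERSION} from BioPAX Level "
            f"{doc.level} source: {Path(source).name}"
        ),
    )
    if len(doc.bio_sources) > 1:
        logger.warning("%s: multiple BioSources; using the first", source)
    if doc.bio_sources:
        first = doc.bio_sources[0]
        if first.taxonomy_id:
            out.organism_urn = f"urn:miriam:taxonomy:{first.taxonomy_id}"
        else:
            logger.warning("%s: BioSource has no taxonomy id", source)
    else:
        logger.warning("%s: no BioSource; organism annotation omitted", source)
    return out


class Converter:
    """Stateful driver for one document conversion (used via :func:`convert`)."""

    def __init__(self, doc: BioPaxDocument, config: ConversionConfig,
                 tables: MappingTables,
                 mapping_table: Optional[ann.IdMappingTable] = None):
        self.doc = doc
        self.config = config
        self.tables = tables
        self.mapping_table = mapping_table
        self.out = init_models(doc, config)
        self.taken: set[str] = {self.out.model_id}
        self._compartments: dict[str, str] = {}          # name -> id
        self._species: dict[tuple[str, str], Species] = {}   # (uri, comp) -> sp
        self._primary: dict[str, tuple[Species, QualitativeSpecies]] = {}
        self._proxies: dict[str, QualitativeSpecies] = {}
        self._reactions: dict[str, Reaction] = {}
        self._transitions: dict[tuple[str, ...], Transition] = {}

    # -- plumbing ----------------------------------------------------------

    def _new_id(self, raw: str) -> str:
        sid = sanitize_id(raw, self.taken)
        self.taken.add(sid)
        return sid

    def _fail_or_skip(self, message: str) -> None:
        if self.config.fallback_policy == "fail":
            raise ConversionError(message)
        logger.warning("%s", message)

    def _compartment_id(self, location: Optional[str]) -> str:
        if not location:
            location = self.config.default_compartment_id
            name = ""
        else:
            name = location
        if location not in self._compartments:
            cid = self._new_id(location)
            self._compartments[location] = cid
            self.out.compartments.append((cid, name))
        return self._compartments[location]

    # -- step 2: entities --------------------------------------------------

    def translate_entity(
            self, entity: BioPaxEntity) -> tuple[Species, QualitativeSpecies]:
        """Create (or return) the species/qualitativeSpecies pair for an
        entity; calling twice never duplicates."""
        if entity.uri in self._primary:
            return self._primary[entity.uri]
        comp = self._compartment_id(entity.cellular_location)
        sbo = assign_sbo_term(entity.entity_class, self.tables)
        sp = Species(id=self._new_id(entity.uri), name=entity.display_name,
                     compartment=comp, sbo_term=sbo)
        qs = QualitativeSpecies(id=self._new_id(f"q_{sp.id}"),
                                name=entity.display_name,
                                compartment=comp, sbo_term=sbo)
        self.out.species.append(sp)
        self.out.qual_species.append(qs)
        self._primary[entity.uri] = (sp, qs)
        self._species[(entity.uri, comp)] = sp
        return sp, qs

    def _species_in(self, entity: BioPaxEntity,
                    location: Optional[str]) -> Species:
        """Species for an entity in a specific compartment; transports across
        compartments yield distinct location-qualified species."""
        primary, _ = self.translate_entity(entity)
        comp = (self._compartment_id(location) if location
                else primary.compartment)
        key = (entity.uri, comp)
        if key not in self._species:
            sp = Species(id=self._new_id(f"{primary.id}_{comp}"),
                         name=entity.display_name, compartment=comp,
                         sbo_term=primary.sbo_term)
            self.out.species.append(sp)
            self._species[key] = sp
        return self._species[key]

    def _pathway_proxy(self, pathway: BioPaxPathway) -> QualitativeSpecies:
        """A pathway acting in a transition is represented by one dedicated
        qualitativeSpecies in the default compartment."""
        if pathway.uri not in self._proxies:
            qs = QualitativeSpecies(
                id=self._new_id(pathway.uri),
                name=pathway.display_name,
                compartment=self._compartment_id(None),
                sbo_term=PATHWAY_PROXY_SBO,
            )
            self.out.qual_species.append(qs)
            self._proxies[pathway.uri] = qs
        return self._proxies[pathway.uri]

    # -- step 3: interactions ---------------------------------------------

    def translate_conversion(self, conv: BioPaxInteraction) -> Reaction:
        """One reaction per conversion, mirroring participants and
        stoichiometric coefficients; memoized by interaction URI."""
        if conv.uri in self._reactions:
            return self._reactions[conv.uri]
        reactants: list[tuple[str, Fraction]] = []
        products: list[tuple[str, Fraction]] = []
        for side, acc in ((conv.left, reactants), (conv.right, products)):
            for part in side:
                obj = self.doc.resolve(part.ref)
                if not isinstance(obj, BioPaxEntity):
                    raise ConversionError(
                        f"{conv.uri}: participant {part.ref} is not a "
                        f"physical entity")
                acc.append((self._species_in(obj, part.location).id,
                            part.stoichiometry))
        rx = Reaction(
            id=self._new_id(conv.uri),
            name=conv.display_name,
            reactants=reactants,
            products=products,
            sbo_term=REACTION_SBO.get(conv.kind.value),
        )
        self.out.reactions.append(rx)
        self._reactions[conv.uri] = rx
        return rx

    def _resolve_controlled(self, ctrl: BioPaxInteraction):
        """Follow the controlled reference, chaining through nested controls
        (e.g. a Modulation whose target is a Catalysis) to the ultimate
        non-control target."""
        seen: set[str] = set()
        ref = ctrl.controlled
        while ref is not None and ref not in seen:
            seen.add(ref)
            obj = self.doc.resolve(ref)
            if isinstance(obj, BioPaxInteraction) and obj.kind in CONTROL_KINDS:
                ref = obj.controlled
                continue
            return obj
        return None

    def _merge_transition(self, key_uri: str, outputs: list[str],
                          inputs: list[tuple[str, Sign]]) -> Transition:
        out_key = tuple(sorted(set(outputs)))
        tr = self._transitions.get(out_key)
        if tr is None:
            tr = Transition(id=self._new_id(f"tr_{key_uri}"),
                            outputs=sorted(set(outputs)))
            self.out.transitions.append(tr)
            self._transitions[out_key] = tr
        current = dict(tr.inputs)
        for qsid, sign in inputs:
            current[qsid] = _combine_signs(current.get(qsid), sign)
        tr.inputs = sorted(current.items())
        return tr

    def translate_control(self, ctrl: BioPaxInteraction) -> None:
        """Translate one control into reaction modifiers and/or a transition."""
        if ctrl.controlled is None:
            self._fail_or_skip(f"{ctrl.uri}: control without controlled; skipped")
            return
        try:
            target = self._resolve_controlled(ctrl)
            if target is None:
                self._fail_or_skip(
                    f"{ctrl.uri}: controlled chain ends unresolved; skipped")
                return
            controllers = [self.doc.resolve(ref) for ref in ctrl.controllers]
        except UnresolvedReferenceError as exc:
            self._fail_or_skip(f"{ctrl.uri}: {exc}; interaction skipped")
            return

        if isinstance(target, BioPaxPathway):
            controlled_kind: ControlledKind = (
                "Pathway" if self.doc.level == 3 else "pathway")
        elif isinstance(target, BioPaxInteraction):
            controlled_kind = target.kind
        else:
            self._fail_or_skip(
                f"{ctrl.uri}: controlled element is a physical entity; skipped")
            return

        sign = control_type_to_sign(ctrl.control_type, self.tables)

        if not controllers:
            if (isinstance(target, BioPaxInteraction)
                    and target.is_conversion):
                self.translate_conversion(target)
            else:
                logger.warning(
                    "%s: control without controllers over a non-conversion; "
                    "nothing emitted", ctrl.uri)
            return

        for controller in controllers:
            if isinstance(controller, BioPaxEntity):
                ctl_kind = ParticipantKind.PHYSICAL_ENTITY
            elif isinstance(controller, BioPaxPathway):
                ctl_kind = ParticipantKind.PATHWAY
            else:
                self._fail_or_skip(
                    f"{ctrl.uri}: controller {controller.uri} is an "
                    f"interaction; skipped")
                continue
            try:
                decision = classify_control(
                    ctl_kind, controlled_kind, self.doc.level, self.tables)
            except UnmappedCombinationError as exc:
                if self.config.fallback_policy == "fail":
                    raise
                logger.warning("%s; defaulting to transition", exc)
                decision = Translation.TRANSITION

            if decision is Translation.REACTION:
                rx = self.translate_conversion(target)
                assert isinstance(controller, BioPaxEntity)
                mod_id = self.translate_entity(controller)[0].id
                if mod_id not in rx.modifiers:
                    rx.modifiers.append(mod_id)
            else:
                self._emit_transition(ctrl, controller, target, sign)

    def _emit_transition(self, ctrl: BioPaxInteraction, controller,
                         target, sign: Sign) -> None:
        if isinstance(controller, BioPaxPathway):
            input_qs = self._pathway_proxy(controller)
        else:
            input_qs = self.translate_entity(controller)[1]
        inputs = [(input_qs.id, sign)]

        if isinstance(target, BioPaxPathway):
            outputs = [self._pathway_proxy(target).id]
        else:
            side = target.right or target.left
            if not side:
                self._fail_or_skip(
                    f"{ctrl.uri}: controlled interaction {target.uri} has no "
                    f"participants to use as transition output; skipped")
                return
            outputs = []
            for part in side:
                obj = self.doc.resolve(part.ref)
                if isinstance(obj, BioPaxEntity):
                    outputs.append(self.translate_entity(obj)[1].id)
            if target.kind is InteractionKind.TEMPLATE_REACTION and target.right:
                # the template itself participates with unspecified effect
                for part in target.left:
                    obj = self.doc.resolve(part.ref)
                    if isinstance(obj, BioPaxEntity):
                        inputs.append(
                            (self.translate_entity(obj)[1].id, Sign.UNKNOWN))
            if not outputs:
                self._fail_or_skip(
                    f"{ctrl.uri}: no usable transition outputs; skipped")
                return
        self._merge_transition(ctrl.uri, outputs, inputs)

    def _standalone_template_reaction(self, ia: BioPaxInteraction) -> None:
        """An uncontrolled template reaction still encodes a qualitative
        production of its products from its template."""
        inputs = []
        outputs = []
        for part in ia.left:
            obj = self.doc.resolve(part.ref)
            if isinstance(obj, BioPaxEntity):
                inputs.append((self.translate_entity(obj)[1].id, Sign.UNKNOWN))
        for part in ia.right:
            obj = self.doc.resolve(part.ref)
            if isinstance(obj, BioPaxEntity):
                outputs.append(self.translate_entity(obj)[1].id)
        if outputs:
            self._merge_transition(ia.uri, outputs, inputs)
        else:
            logger.warning("%s: template reaction without products; skipped",
                           ia.uri)

    # -- step 4: annotation ------------------------------------------------

    def annotate_all(self) -> None:
        for entity in self.doc.entities:
            if entity.uri not in self._primary:
                continue
            component_xrefs = []
            if entity.entity_class is EntityClass.COMPLEX:
                for ref in entity.component_refs:
                    try:
                        obj = self.doc.resolve(ref)
                    except UnresolvedReferenceError:
                        continue
                    if isinstance(obj, BioPaxEntity):
                        component_xrefs.extend(obj.xrefs)
            sp, qs = self._primary[entity.uri]
            for element in (sp, qs):
                ann.annotate_species(element, entity, self.mapping_table,
                                     component_xrefs=component_xrefs)
            # location-qualified copies share the primary's annotation
            for (uri, _), extra in self._species.items():
                if uri == entity.uri and extra is not sp:
                    ann.annotate_species(extra, entity, self.mapping_table,
                                         component_xrefs=component_xrefs)

    # -- orchestration -----------------------------------------------------

    def run(self) -> SbmlDocument:
        for entity in self.doc.entities:
            try:
                self.translate_entity(entity)
            except UnresolvedReferenceError as exc:
                self._fail_or_skip(f"{entity.uri}: {exc}")

        controlled_uris = {
            ia.controlled for ia in self.doc.interactions
            if ia.is_control and ia.controlled
        }
        for ia in self.doc.interactions:
            try:
                if ia.is_conversion:
                    self.translate_conversion(ia)
                elif (ia.kind is InteractionKind.TEMPLATE_REACTION
                      and ia.uri not in controlled_uris):
                    self._standalone_template_reaction(ia)
            except UnresolvedReferenceError as exc:
                self._fail_or_skip(f"{ia.uri}: {exc}; interaction skipped")
            except ConversionError as exc:
                if self.config.fallback_policy == "fail":
                    raise
                logger.warning("%s", exc)
        for ia in self.doc.interactions:
            if ia.is_control:
                self.translate_control(ia)

        self.annotate_all()
        return self.out


def _combine_signs(old: Optional[Sign], new: Sign) -> Sign:
    if old is None or old == new:
        return new
    if Sign.DUAL in (old, new):
        return Sign.DUAL
    if old is Sign.UNKNOWN:
        return new
    if new is Sign.UNKNOWN:
        return old
    return Sign.DUAL  # positive + negative


def convert(doc: BioPaxDocument,
            config: Optional[ConversionConfig] = None,
            tables: Optional[MappingTables] = None,
            mapping_table: Optional[ann.IdMappingTable] = None) -> SbmlDocument:
    """Convert a BioPAX document into one joint SBML core + qual document."""
    config = config or ConversionConfig()
    tables = tables or default_tables()
    if mapping_table is None and config.mapping_table_path is not None:
        mapping_table = ann.IdMappingTable.from_tsv(config.mapping_table_path)
    return Converter(doc, config, tables, mapping_table).run()
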