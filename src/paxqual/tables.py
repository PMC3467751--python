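"""Mapping tables driving the conversion, kept as data rather than code.

Three tables matter:

* ``SBO_BY_CLASS`` — the SBO accession attached to the species made from each
  physical-entity class (material-entity branch of the Systems Biology
  Ontology: polypeptide chain for proteins, simple chemical for small
  molecules, and so on).
* ``DECISION`` — for a Control interaction, whether the (controller kind,
  controlled kind) pair becomes a core-model *reaction* participant or a
  qual-model *transition*, separately for BioPAX Level 2 and Level 3
  vocabularies (16 Level-3 rows, 12 Level-2 rows).
* ``SIGN_BY_CONTROL_TYPE`` — BioPAX controlType tokens to qual input signs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .model import EntityClass


class Translation(str, Enum):
    REACTION = "reaction"
    TRANSITION = "transition"


class Sign(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    DUAL = "dual"
    UNKNOWN = "unknown"


#: SBO accession per entity class (8 rows).
SBO_BY_CLASS: dict[EntityClass, int] = {
    EntityClass.GENE: 354,            # informational molecule segment
    EntityClass.COMPLEX: 253,         # non-covalent complex
    EntityClass.PROTEIN: 252,         # polypeptide chain
    EntityClass.DNA: 251,             # deoxyribonucleic acid
    EntityClass.DNA_REGION: 251,
    EntityClass.RNA: 250,             # ribonucleic acid
    EntityClass.RNA_REGION: 250,
    EntityClass.SMALL_MOLECULE: 247,  # simple chemical
}

#: SBO fallback for classes without a dedicated row (material entity).
DEFAULT_SBO = 240

#: SBO attached to pathway-proxy qualitative species (process).
PATHWAY_PROXY_SBO = 375

#: SBO per conversion kind, attached to the emitted reaction.
REACTION_SBO: dict[str, int] = {
    "BiochemicalReaction": 176,               # biochemical reaction
    "ComplexAssembly": 177,                   # non-covalent binding
    "Transport": 185,                         # transport reaction
    "TransportWithBiochemicalReaction": 185,
    "Degradation": 179,                       # degradation
    "GenericConversion": 182,                 # conversion
}

R = Translation.REACTION
T = Translation.TRANSITION

#: (controller kind, controlled class token, level) -> reaction | transition.
#: Level-3 tokens are capitalised, Level-2 tokens lower-camel-cased, following
#: the respective BioPAX specifications.  ``Pathway``/``pathway`` as a
#: controlled token means a link to another pathway.
DECISION: dict[tuple[str, str, int], Translation] = {
    # --- Level 3: PhysicalEntity controller ---
    ("physical_entity", "BiochemicalReaction", 3): R,
    ("physical_entity", "ComplexAssembly", 3): R,
    ("physical_entity", "Conversion", 3): T,
    ("physical_entity", "Degradation", 3): R,
    ("physical_entity", "Transport", 3): R,
    ("physical_entity", "TransportWithBiochemicalReaction", 3): R,
    ("physical_entity", "Pathway", 3): T,
    ("physical_entity", "TemplateReaction", 3): T,
    # --- Level 3: Pathway controller ---
    ("pathway", "BiochemicalReaction", 3): T,
    ("pathway", "ComplexAssembly", 3): T,
    ("pathway", "Conversion", 3): T,
    ("pathway", "Degradation", 3): T,
    ("pathway", "Pathway", 3): T,
    ("pathway", "TemplateReaction", 3): T,
    ("pathway", "Transport", 3): T,
    ("pathway", "TransportWithBiochemicalReaction", 3): T,
    # --- Level 2: physicalEntity controller ---
    ("physical_entity", "biochemicalReaction", 2): R,
    ("physical_entity", "complexAssembly", 2): R,
    ("physical_entity", "interaction", 2): T,
    ("physical_entity", "pathway", 2): T,
    ("physical_entity", "transport", 2): R,
    ("physical_entity", "transportWithBiochemicalReaction", 2): R,
    # --- Level 2: pathway controller ---
    ("pathway", "biochemicalReaction", 2): T,
    ("pathway", "complexAssembly", 2): T,
    ("pathway", "interaction", 2): T,
    ("pathway", "pathway", 2): T,
    ("pathway", "transportWithBiochemicalReaction", 2): T,
    ("pathway", "transport", 2): T,
}

#: BioPAX controlType token -> qual input sign.  Matching is by prefix, so
#: qualified tokens such as ACTIVATION-ALLOSTERIC or INHIBITION-COMPETITIVE
#: inherit the sign of their base type; DUAL is never produced here — it only
#: arises when opposing controls merge onto one transition input.
SIGN_BY_CONTROL_TYPE: dict[str, Sign] = {
    "ACTIVATION": Sign.POSITIVE,
    "INHIBITION": Sign.NEGATIVE,
}


@dataclass
class MappingTables:
    """Bundle of the conversion tables, overridable for experimentation."""

    sbo_by_class: dict[EntityClass, int] = field(
        default_factory=lambda: dict(SBO_BY_CLASS)
    )
    decision: dict[tuple[str, str, int], Translation] = field(
        default_factory=lambda: dict(DECISION)
    )
    sign_by_control_type: dict[str, Sign] = field(
        default_factory=lambda: dict(SIGN_BY_CONTROL_TYPE)
    )
    default_sbo: int = DEFAULT_SBO

    def __post_init__(self) -> None:
        if len(self.sbo_by_class) != 8:
            raise ValueError("sbo_by_class must contain exactly 8 entity classes")
        n3 = sum(1 for (_, _, lv) in self.decision if lv == 3)
        n2 = sum(1 for (_, _, lv) in self.decision if lv == 2)
        if (n3, n2) != (16, 12):
            raise ValueError(
                f"decision table must have 16 Level-3 and 12 Level-2 rows, "
                f"got {n3} and {n2}"
            )


def default_tables() -> MappingTables:
    return MappingTables()
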