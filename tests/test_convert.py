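from fractions import Fraction

import pytest

from paxqual import (
    BioPaxDocument,
    BioPaxEntity,
    BioPaxInteraction,
    BioPaxPathway,
    BioSource,
    ConversionConfig,
    EntityClass,
    InteractionKind,
    Participant,
    ParticipantKind,
    assign_sbo_term,
    classify_control,
    control_type_to_sign,
    convert,
    default_tables,
    init_models,
    validate_structure,
)
from paxqual.convert import UnmappedCombinationError, _combine_signs
from paxqual.fixtures import FixtureSpec, generate_fixture
from paxqual.sbml import sbml_to_bytes
from paxqual.tables import Sign, Translation

PE = ParticipantKind.PHYSICAL_ENTITY
PW = ParticipantKind.PATHWAY

# The published controller/controlled decision matrix, transcribed row by row
# as the independent oracle for classify_control.
DECISION_ROWS = [
    (PE, "BiochemicalReaction", 3, "reaction"),
    (PE, "ComplexAssembly", 3, "reaction"),
    (PE, "Conversion", 3, "transition"),
    (PE, "Degradation", 3, "reaction"),
    (PE, "Transport", 3, "reaction"),
    (PE, "TransportWithBiochemicalReaction", 3, "reaction"),
    (PE, "Pathway", 3, "transition"),
    (PE, "TemplateReaction", 3, "transition"),
    (PW, "BiochemicalReaction", 3, "transition"),
    (PW, "ComplexAssembly", 3, "transition"),
    (PW, "Conversion", 3, "transition"),
    (PW, "Degradation", 3, "transition"),
    (PW, "Pathway", 3, "transition"),
    (PW, "TemplateReaction", 3, "transition"),
    (PW, "Transport", 3, "transition"),
    (PW, "TransportWithBiochemicalReaction", 3, "transition"),
    (PE, "biochemicalReaction", 2, "reaction"),
    (PE, "complexAssembly", 2, "reaction"),
    (PE, "interaction", 2, "transition"),
    (PE, "pathway", 2, "transition"),
    (PE, "transport", 2, "reaction"),
    (PE, "transportWithBiochemicalReaction", 2, "reaction"),
    (PW, "biochemicalReaction", 2, "transition"),
    (PW, "complexAssembly", 2, "transition"),
    (PW, "interaction", 2, "transition"),
    (PW, "pathway", 2, "transition"),
    (PW, "transportWithBiochemicalReaction", 2, "transition"),
    (PW, "transport", 2, "transition"),
]


def test_decision_table_matches_published_matrix_exactly():
    assert len(DECISION_ROWS) == 28
    for controller, controlled, level, expected in DECISION_ROWS:
        got = classify_control(controller, controlled, level)
        assert got is Translation(expected), (controller, controlled, level)


def test_decision_accepts_interaction_kind_enums():
    assert classify_control(
        PE, InteractionKind.BIOCHEMICAL_REACTION, 3) is Translation.REACTION
    assert classify_control(
        PE, InteractionKind.TEMPLATE_REACTION, 3) is Translation.TRANSITION
    assert classify_control(
        PE, InteractionKind.TRANSPORT, 2) is Translation.REACTION


def test_unmapped_combination_raises():
    with pytest.raises(UnmappedCombinationError):
        classify_control(PE, InteractionKind.GENERIC_INTERACTION, 3)


SBO_ROWS = [
    (EntityClass.GENE, 354),
    (EntityClass.COMPLEX, 253),
    (EntityClass.PROTEIN, 252),
    (EntityClass.DNA, 251),
    (EntityClass.DNA_REGION, 251),
    (EntityClass.RNA, 250),
    (EntityClass.RNA_REGION, 250),
    (EntityClass.SMALL_MOLECULE, 247),
]


@pytest.mark.parametrize("cls, accession", SBO_ROWS)
def test_sbo_assignment(cls, accession):
    assert assign_sbo_term(cls, default_tables()) == accession


def test_generic_entity_gets_material_entity_fallback():
    assert assign_sbo_term(EntityClass.GENERIC, default_tables()) == 240


@pytest.mark.parametrize("token, sign", [
    ("ACTIVATION", Sign.POSITIVE),
    ("ACTIVATION-ALLOSTERIC", Sign.POSITIVE),
    ("activation", Sign.POSITIVE),
    ("INHIBITION", Sign.NEGATIVE),
    ("INHIBITION-COMPETITIVE", Sign.NEGATIVE),
    (None, Sign.UNKNOWN),
    ("", Sign.UNKNOWN),
    ("SOMETHING-ELSE", Sign.UNKNOWN),
])
def test_control_type_to_sign(token, sign):
    assert control_type_to_sign(token) is sign


def test_sign_merge_rules():
    assert _combine_signs(Sign.POSITIVE, Sign.NEGATIVE) is Sign.DUAL
    assert _combine_signs(Sign.POSITIVE, Sign.UNKNOWN) is Sign.POSITIVE
    assert _combine_signs(Sign.UNKNOWN, Sign.NEGATIVE) is Sign.NEGATIVE
    assert _combine_signs(None, Sign.UNKNOWN) is Sign.UNKNOWN
    assert _combine_signs(Sign.DUAL, Sign.POSITIVE) is Sign.DUAL


# --- step 1 ----------------------------------------------------------------


def test_organism_urn_from_biosource():
    doc = BioPaxDocument(level=3, bio_sources=[
        BioSource(name="Homo sapiens", taxonomy_id="9606")])
    assert init_models(doc).organism_urn == "urn:miriam:taxonomy:9606"


def test_missing_biosource_means_no_organism():
    assert init_models(BioPaxDocument(level=3)).organism_urn is None


def test_first_of_two_biosources_wins():
    doc = generate_fixture(FixtureSpec("two-biosources", 3))
    assert convert(doc).organism_urn == "urn:miriam:taxonomy:9606"


# --- step 2 ----------------------------------------------------------------


def test_entity_becomes_species_and_qual_species_in_its_compartment(
        inhibition_doc):
    out = convert(inhibition_doc)
    assert len(out.species) == 1
    # protein + pathway proxy on the qualitative side
    assert len(out.qual_species) == 2
    assert out.species[0].sbo_term == 252


def test_default_compartment_when_location_unknown():
    doc = generate_fixture(FixtureSpec("missing-cellular-location", 3))
    out = convert(doc)
    assert out.species[0].compartment == "default"
    custom = convert(doc, ConversionConfig(default_compartment_id="cell"))
    assert custom.species[0].compartment == "cell"


def test_location_becomes_named_compartment():
    doc = generate_fixture(FixtureSpec("entity-protein", 3))
    out = convert(doc)
    assert ("cytoplasm", "cytoplasm") in out.compartments
    assert out.species[0].compartment == "cytoplasm"


def test_no_duplicate_species_for_reused_entity():
    doc = generate_fixture(FixtureSpec("duplicate-entity-use", 3))
    out = convert(doc)
    assert len(out.species) == len(doc.entities) == 3
    assert len(out.reactions) == 2


# --- step 3 ----------------------------------------------------------------


def test_stoichiometry_preserved():
    doc = generate_fixture(FixtureSpec("stoichiometric-reaction", 3))
    out = convert(doc)
    rx = out.reactions[0]
    assert sorted(c for _, c in rx.reactants) == [Fraction(1), Fraction(2)]
    assert [c for _, c in rx.products] == [Fraction(1)]


def test_degradation_reaction_has_no_products():
    doc = generate_fixture(FixtureSpec("degradation-standalone", 3))
    out = convert(doc)
    rx = out.reactions[0]
    assert len(rx.reactants) == 1 and rx.products == []
    assert rx.sbo_term == 179
    assert validate_structure(out).ok


def test_transport_links_location_specific_species():
    doc = generate_fixture(FixtureSpec("transport-two-compartments", 3))
    out = convert(doc)
    rx = out.reactions[0]
    by_id = {s.id: s for s in out.species}
    assert by_id[rx.reactants[0][0]].compartment == "cytoplasm"
    assert by_id[rx.products[0][0]].compartment == "nucleus"


def test_catalysis_attaches_enzyme_as_modifier():
    doc = generate_fixture(FixtureSpec("pe-controls-biochemicalreaction", 3))
    out = convert(doc)
    assert len(out.transitions) == 0
    assert len(out.reactions) == 1
    assert len(out.reactions[0].modifiers) == 1


def test_inhibition_of_pathway_becomes_negative_transition(inhibition_doc):
    out = convert(inhibition_doc)
    (tr,) = out.transitions
    assert tr.inputs == [("q_p1", Sign.NEGATIVE)]
    proxy = [q for q in out.qual_species if q.id in tr.outputs]
    assert proxy and proxy[0].name == "W"


def test_opposing_controls_merge_to_dual():
    doc = generate_fixture(FixtureSpec("opposing-controls", 3))
    out = convert(doc)
    (tr,) = out.transitions
    signs = dict(tr.inputs)
    assert signs["q_ctl"] is Sign.DUAL
    # the template participates with unspecified sign
    assert signs["q_template"] is Sign.UNKNOWN


def test_control_without_controlled_is_skipped():
    doc = BioPaxDocument(level=3, entities=[
        BioPaxEntity(uri="#p", entity_class=EntityClass.PROTEIN)],
        interactions=[BioPaxInteraction(
            uri="#c", kind=InteractionKind.CONTROL, controllers=["#p"])])
    out = convert(doc)
    assert out.transitions == [] and out.reactions == []
    assert len(out.species) == 1


def test_modulation_of_catalysis_chains_to_final_target():
    doc = BioPaxDocument(
        level=3,
        entities=[
            BioPaxEntity(uri="#e", entity_class=EntityClass.PROTEIN),
            BioPaxEntity(uri="#m", entity_class=EntityClass.PROTEIN),
            BioPaxEntity(uri="#a", entity_class=EntityClass.PROTEIN),
            BioPaxEntity(uri="#b", entity_class=EntityClass.PROTEIN),
        ],
        interactions=[
            BioPaxInteraction(uri="#rx",
                              kind=InteractionKind.BIOCHEMICAL_REACTION,
                              left=[Participant("#a")],
                              right=[Participant("#b")]),
            BioPaxInteraction(uri="#cat", kind=InteractionKind.CATALYSIS,
                              controllers=["#e"], controlled="#rx",
                              control_type="ACTIVATION"),
            BioPaxInteraction(uri="#mod", kind=InteractionKind.MODULATION,
                              controllers=["#m"], controlled="#cat",
                              control_type="INHIBITION"),
        ],
    )
    out = convert(doc)
    (rx,) = out.reactions
    # both the enzyme and the modulator end up attached to the reaction
    assert set(rx.modifiers) == {"e", "m"}


def test_unresolved_reference_policy():
    doc = BioPaxDocument(level=3, entities=[
        BioPaxEntity(uri="#p", entity_class=EntityClass.PROTEIN)],
        interactions=[BioPaxInteraction(
            uri="#c", kind=InteractionKind.CONTROL, controllers=["#p"],
            controlled="#ghost")])
    out = convert(doc)  # warn_skip: drops the broken control
    assert out.transitions == []
    from paxqual.convert import ConversionError

    with pytest.raises((ConversionError, KeyError)):
        convert(doc, ConversionConfig(fallback_policy="fail"))


# --- whole-document properties --------------------------------------------


def test_every_entity_is_present_and_output_is_valid(all_fixture_docs):
    """Completeness + structural validity across the whole fixture matrix."""
    for level, scenario, doc in all_fixture_docs:
        out = convert(doc)
        assert len(out.species) >= len(doc.entities), scenario
        primary_qual = [q for q in out.qual_species]
        assert len(primary_qual) >= len(doc.entities), scenario
        report = validate_structure(out)
        assert report.ok, f"{scenario} (L{level}): {report}"
        for tr in out.transitions:
            for _, sign in tr.inputs:
                assert sign in (Sign.POSITIVE, Sign.NEGATIVE, Sign.DUAL,
                                Sign.UNKNOWN)


def test_conversion_is_deterministic(all_fixture_docs):
    for _, scenario, doc in all_fixture_docs:
        assert sbml_to_bytes(convert(doc)) == sbml_to_bytes(convert(doc)), \
            scenario


def test_empty_document_converts_to_valid_empty_model():
    out = convert(BioPaxDocument(level=3))
    assert not out.species and not out.reactions and not out.transitions
    assert validate_structure(out).ok
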