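from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st
from lxml import etree

from paxqual import (
    QualitativeSpecies,
    Reaction,
    SbmlDocument,
    Species,
    Transition,
    sanitize_id,
    sbml_to_bytes,
    validate_sbml_file,
    validate_structure,
    write_sbml,
)
from paxqual.sbml import SID_PATTERN, urn_to_url
from paxqual.tables import Sign


@pytest.mark.parametrize("raw, expected", [
    ("http://pid.nci.nih.gov/biopax#pid_42", "pid_42"),
    ("14-3-3", "_14_3_3"),
    ("plain", "plain"),
    ("http://x.org/path/to/thing", "thing"),
])
def test_sanitize_id_examples(raw, expected):
    assert sanitize_id(raw) == expected


def test_sanitize_id_collision_suffixes():
    taken = {"pid_42"}
    assert sanitize_id("pid_42", taken) == "pid_42_2"
    taken.add("pid_42_2")
    assert sanitize_id("x#pid_42", taken) == "pid_42_3"


@settings(max_examples=100, deadline=None, derandomize=True)
@given(raw=st.text(min_size=1, max_size=40))
def test_sanitize_id_always_yields_valid_sid(raw):
    assert SID_PATTERN.match(sanitize_id(raw))


def _sample_doc() -> SbmlDocument:
    return SbmlDocument(
        model_id="m",
        compartments=[("default", "")],
        species=[Species(id="a", compartment="default", sbo_term=252),
                 Species(id="b", compartment="default", sbo_term=247)],
        reactions=[Reaction(id="r", reactants=[("a", Fraction(1))],
                            products=[("b", Fraction(2))])],
        qual_species=[QualitativeSpecies(id="qa", compartment="default")],
        transitions=[Transition(id="t", inputs=[("qa", Sign.POSITIVE)],
                                outputs=["qa"])],
        provenance="tool test",
    )


def test_writer_is_byte_deterministic():
    assert sbml_to_bytes(_sample_doc()) == sbml_to_bytes(_sample_doc())


def test_written_file_passes_file_validator(tmp_path):
    path = write_sbml(_sample_doc(), tmp_path / "m.sbml.xml")
    assert validate_sbml_file(path).ok


def test_no_empty_listof_elements_serialized():
    empty = SbmlDocument(model_id="m")
    root = etree.fromstring(sbml_to_bytes(empty))
    assert not [el for el in root.iter()
                if etree.QName(el).localname.startswith("listOf")]


def test_schema_element_order(tmp_path):
    root = etree.fromstring(sbml_to_bytes(_sample_doc()))
    model = root[0]
    names = [etree.QName(child).localname for child in model]
    assert names == ["notes", "listOfCompartments", "listOfSpecies",
                     "listOfReactions", "listOfQualitativeSpecies",
                     "listOfTransitions"]


def test_qual_namespace_and_required_flag():
    root = etree.fromstring(sbml_to_bytes(_sample_doc()))
    qual = "http://www.sbml.org/sbml/level3/version1/qual/version1"
    assert root.get(f"{{{qual}}}required") == "false"


def test_urn_to_url_form():
    assert (urn_to_url("urn:miriam:obo.go:GO%3A0006915")
            == "http://identifiers.org/obo.go/GO:0006915")


# --- validator defect detection --------------------------------------------


def test_missing_species_detected():
    doc = _sample_doc()
    doc.reactions[0].reactants.append(("ghost", Fraction(1)))
    codes = {i.code for i in validate_structure(doc).issues}
    assert codes == {"MISSING_SPECIES"}


def test_duplicate_id_detected():
    doc = _sample_doc()
    doc.species.append(Species(id="a", compartment="default"))
    codes = {i.code for i in validate_structure(doc).issues}
    assert "DUPLICATE_ID" in codes


def test_dangling_compartment_detected():
    doc = _sample_doc()
    doc.species[0].compartment = "nowhere"
    codes = {i.code for i in validate_structure(doc).issues}
    assert codes == {"DANGLING_REF"}


def test_transition_without_outputs_detected():
    doc = _sample_doc()
    doc.transitions[0].outputs = []
    codes = {i.code for i in validate_structure(doc).issues}
    assert codes == {"EMPTY_LISTOF"}


def test_write_refuses_invalid_document(tmp_path):
    doc = _sample_doc()
    doc.species.append(Species(id="a", compartment="default"))
    with pytest.raises(ValueError):
        write_sbml(doc, tmp_path / "bad.xml")


def test_file_validator_flags_hand_broken_files(tmp_path):
    good = sbml_to_bytes(_sample_doc()).decode()

    dup = good.replace('<species id="b"', '<species id="a"', 1)
    path = tmp_path / "dup.xml"
    path.write_text(dup)
    assert {"DUPLICATE_ID"} <= {i.code for i in validate_sbml_file(path).issues}

    empty = good.replace(
        "<listOfCompartments>\n      "
        '<compartment id="default" constant="true"/>\n    '
        "</listOfCompartments>",
        "<listOfCompartments></listOfCompartments>")
    path = tmp_path / "empty.xml"
    path.write_text(empty)
    codes = {i.code for i in validate_sbml_file(path).issues}
    assert "EMPTY_LISTOF" in codes

    bad_sign = good.replace('qual:sign="positive"', 'qual:sign="sideways"')
    path = tmp_path / "sign.xml"
    path.write_text(bad_sign)
    assert {"BAD_SIGN"} <= {i.code for i in validate_sbml_file(path).issues}


def test_file_validator_flags_bad_order(tmp_path):
    # species list moved after reactions: schema-order violation
    doc = _sample_doc()
    xml = sbml_to_bytes(doc).decode()
    species_block = xml[xml.index("<listOfSpecies>"):
                        xml.index("</listOfSpecies>") + len("</listOfSpecies>")]
    moved = xml.replace(species_block, "")
    moved = moved.replace("</listOfReactions>",
                          "</listOfReactions>" + species_block)
    path = tmp_path / "order.xml"
    path.write_text(moved)
    assert "BAD_ORDER" in {i.code for i in validate_sbml_file(path).issues}
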