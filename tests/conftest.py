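import logging

import pytest

from paxqual import BioPaxDocument, BioPaxEntity, BioPaxInteraction, \
    BioPaxPathway, EntityClass, InteractionKind
from paxqual.fixtures import FixtureSpec, generate_fixture, scenario_names


def doc_key(doc: BioPaxDocument):
    """Order-insensitive fingerprint of a document's modeled content."""
    return (
        doc.level,
        sorted((e.uri, e.entity_class, e.display_name, e.cellular_location,
                frozenset(e.xrefs), frozenset(e.component_refs))
               for e in doc.entities),
        sorted((i.uri, i.kind, frozenset(i.left), frozenset(i.right),
                frozenset(i.controllers), i.controlled, i.control_type)
               for i in doc.interactions),
        sorted((p.uri, frozenset(p.component_interaction_refs))
               for p in doc.pathways),
        sorted((b.name, b.taxonomy_id) for b in doc.bio_sources),
    )


@pytest.fixture(autouse=True)
def _quiet_logs():
    # fixture conversions deliberately exercise warning paths
    logging.disable(logging.WARNING)
    yield
    logging.disable(logging.NOTSET)


@pytest.fixture(scope="session")
def all_fixture_docs() -> list[tuple[int, str, BioPaxDocument]]:
    """Every scenario document of both levels, generated once."""
    out = []
    for level in (2, 3):
        for scenario in scenario_names(level):
            out.append((level, scenario,
                        generate_fixture(FixtureSpec(scenario, level))))
    return out


@pytest.fixture
def inhibition_doc() -> BioPaxDocument:
    """One protein inhibiting one pathway — the minimal transition case."""
    return BioPaxDocument(
        level=3,
        entities=[BioPaxEntity(uri="#p1", entity_class=EntityClass.PROTEIN,
                               display_name="P")],
        pathways=[BioPaxPathway(uri="#pw1", display_name="W")],
        interactions=[BioPaxInteraction(
            uri="#c1", kind=InteractionKind.CONTROL, controllers=["#p1"],
            controlled="#pw1", control_type="INHIBITION")],
    )
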