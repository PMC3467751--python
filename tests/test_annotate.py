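import pytest
from hypothesis import given, settings, strategies as st

from paxqual import (
    BioPaxEntity,
    EntityClass,
    IdMappingTable,
    Xref,
    annotate_species,
    mine_entrez_gene,
    normalize_db_name,
    xref_to_urn,
)
from paxqual.annotate import URN_PATTERN
from paxqual.sbml import Species


@pytest.mark.parametrize("raw, token", [
    ("UniProt", "uniprot"),
    ("UniProtKB", "uniprot"),
    ("uniprot", "uniprot"),
    ("Swiss-Prot", "uniprot"),
    ("Entrez Gene", "entrez.gene"),
    ("EntrezGene", "entrez.gene"),
    ("LocusLink", "entrez.gene"),
    ("OMIM", "omim"),
    ("Ensembl", "ensembl"),
    ("ChEBI", "chebi"),
    ("DrugBank", "drugbank"),
    ("Gene Ontology", "obo.go"),
    ("GO", "obo.go"),
    ("HGNC", "hgnc"),
    ("PubChem", "pubchem.compound"),
    ("3DMET", "3dmet"),
    ("NCBI Taxonomy", "taxonomy"),
    ("PDBeChem", "pdbechem"),
    ("GlycomeDB", "glycomedb"),
    ("LipidBank", "lipidbank"),
    ("EC-Numbers", "ec-code"),
    ("KEGG Gene", "kegg.genes"),
    ("KEGG Glycan", "kegg.glycan"),
    ("KEGG Reaction", "kegg.reaction"),
    ("KEGG Compound", "kegg.compound"),
    ("KEGG Drug", "kegg.drug"),
    ("KEGG Pathway", "kegg.pathway"),
    ("KEGG Orthology", "kegg.orthology"),
    ("MadeUpDB", "unknown"),
])
def test_dialect_normalization(raw, token):
    assert normalize_db_name(raw) == token


def test_normalization_is_case_and_punctuation_insensitive():
    for variant in ("uniprotkb", "UNIPROT-KB", "uni prot kb"):
        assert normalize_db_name(variant) == "uniprot"


@pytest.mark.parametrize("xref, urn", [
    (Xref("UniProt", "P12345"), "urn:miriam:uniprot:P12345"),
    (Xref("Entrez Gene", "1950"), "urn:miriam:entrez.gene:1950"),
    (Xref("GO", "GO:0006915"), "urn:miriam:obo.go:GO%3A0006915"),
    (Xref("MadeUpDB", "x"), None),
])
def test_xref_to_urn(xref, urn):
    assert xref_to_urn(xref) == urn


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    db=st.sampled_from(["UniProt", "Entrez Gene", "ChEBI", "GO", "HGNC",
                        "KEGG Pathway", "EC"]),
    ident=st.text(
        alphabet=st.characters(min_codepoint=33, max_codepoint=126),
        min_size=1, max_size=20),
)
def test_every_emitted_urn_is_well_formed(db, ident):
    urn = xref_to_urn(Xref(db, ident))
    assert urn is not None and URN_PATTERN.match(urn)


@pytest.fixture
def table(tmp_path):
    tsv = tmp_path / "map.tsv"
    tsv.write_text(
        "symbol\tentrez_gene\textra1\textra2\n"
        "TP53\t7157\tensembl:ENSG00000141510\tuniprot:P04637\n"
        "MDM2\t4193\tensembl:ENSG00000135679\t\n"
    )
    return IdMappingTable.from_tsv(tsv)


def test_mapping_table_lookup(table):
    assert table.entrez_for_symbol("TP53") == "7157"
    assert table.entrez_for_symbol("NOPE") is None
    assert table.extras_for_entrez("7157") == {
        "ensembl": "ENSG00000141510", "uniprot": "P04637"}


def test_mine_entrez_prefers_direct_xref(table):
    ent = BioPaxEntity(uri="#e", entity_class=EntityClass.PROTEIN,
                       display_name="TP53",
                       xrefs=[Xref("Entrez Gene", "999")])
    assert mine_entrez_gene(ent, table) == "999"


def test_mine_entrez_falls_back_to_symbol(table):
    ent = BioPaxEntity(uri="#e", entity_class=EntityClass.PROTEIN,
                       display_name="TP53")
    assert mine_entrez_gene(ent, table) == "7157"
    none = BioPaxEntity(uri="#n", entity_class=EntityClass.PROTEIN,
                        display_name="UNKNOWN_GENE")
    assert mine_entrez_gene(none, table) is None


def test_annotation_counts_and_augmentation(table):
    ent = BioPaxEntity(uri="#e", entity_class=EntityClass.PROTEIN,
                       display_name="TP53",
                       xrefs=[Xref("UniProt", "P04637"),
                              Xref("Entrez Gene", "7157")])
    sp = Species(id="e")
    annotate_species(sp, ent, table)
    (term,) = sp.cv_terms
    # uniprot + entrez from xrefs, ensembl from the table (uniprot dedupes)
    assert set(term.urns) == {
        "urn:miriam:uniprot:P04637",
        "urn:miriam:entrez.gene:7157",
        "urn:miriam:ensembl:ENSG00000141510",
    }


def test_annotation_without_xrefs_is_a_no_op():
    ent = BioPaxEntity(uri="#e", entity_class=EntityClass.PROTEIN,
                       display_name="ZZZZ")
    sp = Species(id="e")
    annotate_species(sp, ent, None)
    assert sp.cv_terms == []


def test_annotation_is_idempotent(table):
    ent = BioPaxEntity(uri="#e", entity_class=EntityClass.PROTEIN,
                       display_name="TP53",
                       xrefs=[Xref("UniProt", "P04637")])
    sp = Species(id="e")
    annotate_species(sp, ent, table)
    once = list(sp.cv_terms)
    annotate_species(sp, ent, table)
    assert sp.cv_terms == once


def test_complex_components_become_has_part_terms():
    ent = BioPaxEntity(uri="#c", entity_class=EntityClass.COMPLEX,
                       component_refs=["#a", "#b"])
    sp = Species(id="c")
    annotate_species(sp, ent, None,
                     component_xrefs=[Xref("UniProt", "P1"),
                                      Xref("UniProt", "P2")])
    (term,) = sp.cv_terms
    assert term.qualifier.value == "has_part"
    assert len(term.urns) == 2
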