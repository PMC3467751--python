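"""Cross-reference normalization and MIRIAM annotation.

BioPAX files name the same database inconsistently ("UniProt", "UniProtKB",
"SwissProt", ...).  This module normalizes those dialects to canonical MIRIAM
collection tokens, renders cross-references as ``urn:miriam:<collection>:<id>``
URNs, and augments species with identifiers from an offline tab-separated
mapping table (gene symbol, Entrez Gene id, and further collection ids).  The
table is a pluggable, network-free identifier resolver: any source of
symbol-to-id mappings can be loaded into it.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional
from urllib.parse import quote

import pandas as pd

from .model import BioPaxEntity, Xref

logger = logging.getLogger(__name__)

URN_PATTERN = re.compile(r"^urn:miriam:[A-Za-z0-9._\-]+:[A-Za-z0-9._\-%~]+$")


class Qualifier(str, Enum):
    """BioModels biology qualifier used on a controlled-vocabulary term."""

    IS = "is"
    IS_DESCRIBED_BY = "is_described_by"
    OCCURS_IN = "occurs_in"
    HAS_PART = "has_part"


@dataclass(frozen=True)
class CvTerm:
    """A qualified set of MIRIAM URNs attached to an SBML element."""

    qualifier: Qualifier
    urns: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.urns:
            raise ValueError("CvTerm requires at least one URN")
        for urn in self.urns:
            if not URN_PATTERN.match(urn):
                raise ValueError(f"not a MIRIAM URN: {urn!r}")


def _squash(name: str) -> str:
    """Lower-case and strip punctuation/whitespace for dialect lookup."""
    return re.sub(r"[^a-z0-9]", "", name.lower())


# Dialect table: squashed database name -> MIRIAM collection token.  Covers
# the databases the annotation step supports (Entrez Gene, Omim, Ensembl,
# UniProt, ChEBI, DrugBank, Gene Ontology, HGNC, PubChem, 3DMET, NCBI
# Taxonomy, PDBeChem, GlycomeDB, LipidBank, EC numbers and the KEGG
# sub-databases) plus the spellings seen in the wild for each.
_DIALECTS: dict[str, str] = {}


def _add(collection: str, *names: str) -> None:
    for name in names:
        _DIALECTS[_squash(name)] = collection


_add("entrez.gene", "Entrez Gene", "EntrezGene", "Entrez-Gene", "NCBI Gene",
     "ncbigene", "LocusLink", "LL")
_add("omim", "OMIM", "MIM", "Online Mendelian Inheritance in Man")
_add("ensembl", "Ensembl", "EnsemblGenomes")
_add("uniprot", "UniProt", "UniProtKB", "UniProt Knowledgebase", "SwissProt",
     "Swiss-Prot", "UniProtKB/Swiss-Prot", "TrEMBL")
_add("chebi", "ChEBI", "CHEBI",
     "Chemical Entities of Biological Interest")
_add("drugbank", "DrugBank")
_add("obo.go", "GO", "Gene Ontology", "GeneOntology")
_add("hgnc", "HGNC", "HUGO", "HGNC Symbol")
_add("pubchem.compound", "PubChem", "PubChem Compound", "PubChem-compound",
     "CID")
_add("pubchem.substance", "PubChem Substance", "PubChem-substance", "SID")
_add("3dmet", "3DMET")
_add("taxonomy", "Taxonomy", "NCBI Taxonomy", "taxon", "NEWT")
_add("pdbechem", "PDBeChem", "PDB-CCD")
_add("glycomedb", "GlycomeDB")
_add("lipidbank", "LipidBank")
_add("ec-code", "EC", "EC Number", "EC-Numbers", "Enzyme Nomenclature",
     "IntEnz", "EC-code")
_add("kegg.genes", "KEGG Gene", "KEGG Genes")
_add("kegg.glycan", "KEGG Glycan")
_add("kegg.reaction", "KEGG Reaction")
_add("kegg.compound", "KEGG Compound", "KEGG Ligand")
_add("kegg.drug", "KEGG Drug")
_add("kegg.pathway", "KEGG Pathway")
_add("kegg.orthology", "KEGG Orthology", "KO")

UNKNOWN = "unknown"


def normalize_db_name(db_raw: str) -> str:
    """Map a verbatim database name to its MIRIAM collection token.

    Lookup is case- and punctuation-insensitive; unmatched names return
    ``"unknown"``.
    """
    if not db_raw:
        raise ValueError("empty database name")
    return _DIALECTS.get(_squash(db_raw), UNKNOWN)


def xref_to_urn(xref: Xref) -> Optional[str]:
    """Render a cross-reference as a MIRIAM URN, or None if the database is
    not recognized (logged).  Identifiers are percent-encoded so that e.g.
    ``GO:0006915`` becomes ``GO%3A0006915`` as the URN grammar requires."""
    collection = normalize_db_name(xref.db_raw)
    if collection == UNKNOWN:
        logger.warning("unknown xref database %r (id %s); skipped",
                       xref.db_raw, xref.id_value)
        return None
    return f"urn:miriam:{collection}:{quote(xref.id_value, safe='')}"


@dataclass
class IdMappingTable:
    """Offline identifier-mapping table.

    Rows map a gene symbol to its Entrez Gene id and to further collection
    ids (``extra`` maps MIRIAM collection token -> identifier).  Loaded from
    a TSV with columns ``symbol``, ``entrez_gene``, then ``collection:id``
    pairs in the remaining cells.
    """

    frame: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["symbol", "entrez_gene"])
    )

    def __post_init__(self) -> None:
        if not {"symbol", "entrez_gene"} <= set(self.frame.columns):
            raise ValueError("mapping table needs 'symbol' and 'entrez_gene' columns")
        ids = self.frame["entrez_gene"].astype(str)
        if ids.duplicated().any():
            raise ValueError("entrez_gene ids must be unique per row")
        self._by_symbol = {
            str(row.symbol): row for row in self.frame.itertuples(index=False)
        }
        self._by_entrez = {
            str(row.entrez_gene): row for row in self.frame.itertuples(index=False)
        }

    @classmethod
    def from_tsv(cls, path: str | Path) -> "IdMappingTable":
        raw = pd.read_csv(path, sep="\t", dtype=str, header=0)
        records = []
        extra_cols: list[str] = []
        for _, row in raw.iterrows():
            rec = {"symbol": row["symbol"], "entrez_gene": row["entrez_gene"]}
            for cell in row.drop(["symbol", "entrez_gene"]).dropna():
                collection, _, ident = str(cell).partition(":")
                if not ident:
                    continue
                rec[collection] = ident
                if collection not in extra_cols:
                    extra_cols.append(collection)
            records.append(rec)
        frame = pd.DataFrame.from_records(
            records, columns=["symbol", "entrez_gene", *extra_cols]
        )
        return cls(frame)

    def entrez_for_symbol(self, symbol: str) -> Optional[str]:
        row = self._by_symbol.get(symbol)
        return str(row.entrez_gene) if row is not None else None

    def extras_for_entrez(self, entrez_id: str) -> dict[str, str]:
        """Further (collection -> id) mappings for a given Entrez Gene id."""
        row = self._by_entrez.get(str(entrez_id))
        if row is None:
            return {}
        out = {}
        for col, value in row._asdict().items():
            if col in ("symbol", "entrez_gene") or pd.isna(value):
                continue
            out[col] = str(value)
        return out


def mine_entrez_gene(entity: BioPaxEntity,
                     table: Optional[IdMappingTable] = None) -> Optional[str]:
    """Find an Entrez Gene id for an entity.

    Preference order: a direct Entrez Gene cross-reference on the entity;
    otherwise the entity's gene-symbol-like display name (or an HGNC xref)
    resolved through the mapping table; otherwise None.
    """
    for xref in entity.xrefs:
        if normalize_db_name(xref.db_raw) == "entrez.gene":
            return xref.id_value
    if table is None:
        return None
    symbols = []
    for xref in entity.xrefs:
        if normalize_db_name(xref.db_raw) == "hgnc":
            symbols.append(xref.id_value)
    if entity.display_name:
        symbols.append(entity.display_name)
    for symbol in symbols:
        entrez = table.entrez_for_symbol(symbol)
        if entrez is not None:
            return entrez
    return None


def annotate_species(species, entity: BioPaxEntity,
                     table: Optional[IdMappingTable] = None,
                     component_xrefs: Optional[list[Xref]] = None) -> None:
    """Attach MIRIAM CV terms to a species (idempotently).

    All convertible entity xrefs become ``is``-qualified URNs; a mined Entrez
    Gene id and the mapping-table extras for it are added alongside; complex
    components' xrefs (passed by the converter) become ``has_part`` terms.
    Re-annotating produces the identical term set.
    """
    is_urns: set[str] = set()
    for xref in entity.xrefs:
        urn = xref_to_urn(xref)
        if urn is not None:
            is_urns.add(urn)
    entrez = mine_entrez_gene(entity, table)
    if entrez is not None:
        is_urns.add(f"urn:miriam:entrez.gene:{quote(entrez, safe='')}")
        if table is not None:
            for collection, ident in table.extras_for_entrez(entrez).items():
                is_urns.add(f"urn:miriam:{collection}:{quote(ident, safe='')}")

    part_urns: set[str] = set()
    for xref in component_xrefs or []:
        urn = xref_to_urn(xref)
        if urn is not None:
            part_urns.add(urn)

    terms = []
    if is_urns:
        terms.append(CvTerm(Qualifier.IS, tuple(sorted(is_urns))))
    if part_urns:
        terms.append(CvTerm(Qualifier.HAS_PART, tuple(sorted(part_urns))))

    # replace any previous annotation with these qualifiers -> idempotent
    kept = [t for t in species.cv_terms
            if t.qualifier not in (Qualifier.IS, Qualifier.HAS_PART)]
    species.cv_terms = kept + terms
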