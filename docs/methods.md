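# Methods

## Scope and representation

`paxqual` models the subset of the BioPAX ontology needed for conversion to
SBML: physical entities (proteins, complexes, nucleic acids and their Level-3
region classes, small molecules, genes), conversions with stoichiometric
participants, controls (including catalysis, modulation and template-reaction
regulation), pathways, cross-references and the organism (`BioSource`).
Experimental-evidence classes, binding features and sequence-level detail are
out of scope. Levels 2 and 3 share one in-memory representation; classes that
only exist in Level 3 (`Gene`, `DnaRegion`, `RnaRegion`, `Degradation`,
`TemplateReaction*`) are rejected at construction time on a level-2 document,
so level consistency is impossible to violate downstream.

Reading uses rdflib, which absorbs the RDF/XML variability found in database
exports (rdf:ID vs rdf:about, nested vs referenced resources). The two level
dialects — Level 2's `UPPER-CASE` properties and participant wrapper objects,
Level 3's camelCase properties and `Stoichiometry` objects — are normalized
through per-level property alias tables. Rare interaction classes
(`MolecularInteraction`, `GeneticInteraction`, `physicalInteraction`) fold
into the generic interaction with a warning; unmodeled helper classes are
ignored. Because an RDF graph has no element order, the reader ranks subjects
by their first appearance in the raw XML (a cheap lxml scan) and falls back
to URI order, so "first BioSource in document order" and output ordering are
well defined and deterministic.

Writing BioPAX and SBML goes through lxml with explicit element ordering
rather than rdflib's serializer, because byte-identical output for identical
input is a converter guarantee here (it makes regression diffs and
content-addressed caching trivial). For the same reason the provenance notes
block records tool name, version and source file but no wall-clock
timestamp by default; a caller can supply one explicitly.

## The decision table

A Control is translated into a core-model reaction participant exactly when
the controlled element is itself an unambiguous biochemical event and the
controller is a physical entity: enzyme catalysis of a biochemical reaction,
complex assembly, transport, degradation. Everything else — pathways on
either side, template reactions, generic conversions/interactions — has no
faithful stoichiometric reading and becomes a signed qual transition. The
full 16-row Level-3 and 12-row Level-2 matrix lives as data in
`paxqual.tables.DECISION`; `classify_control` is a pure lookup, and the
fixture catalogue is derived from the same table so conformance coverage
cannot drift. Combinations outside the matrix default to a transition with a
warning (or an error under the `fail` policy).

Design choices the mapping itself leaves open:

* **Pathway proxy.** A pathway acting as controller or controlled is
  represented by one dedicated qualitativeSpecies (default compartment,
  SBO:0000375 *process*), since qual transitions connect qualitativeSpecies,
  not models.
* **Transition outputs.** For a controlled conversion or template reaction
  the outputs are the product-side qualitativeSpecies (falling back to the
  substrate side for product-free events such as degradation); for a
  controlled pathway, the pathway proxy.
* **Template reactions.** The template participates as an extra input with
  sign `unknown`; an uncontrolled template reaction still emits its
  template → product transition so the regulatory structure is not lost.
* **Nested controls.** A control whose controlled element is another control
  (e.g. modulation of a catalysis) chains to the ultimate non-control
  target; a cycle or dangling chain is skipped with a warning.
* **Sign merging.** Controls targeting the same output set merge into one
  transition; duplicate inputs combine as
  {positive, negative} → dual, X ∪ unknown → X, dual absorbing.
* **Controller-less controls.** The controlled conversion's reaction is
  still emitted (without modifiers); a controller-less control over a
  pathway emits nothing, with a warning.
* **Species identity is entity × compartment.** SBML species are
  compartment-bound, so a transport across compartments references distinct
  location-qualified species; the entity's primary species/qualitativeSpecies
  pair is unique, which is what the no-duplicates guarantee covers.
* **Complexes** are single species (with their own SBO term); component
  cross-references surface as `hasPart` CV terms. Component lists are kept
  one level deep; deeper nesting is logged.
* **SBO fallback** for entity classes without a dedicated row is
  SBO:0000240 (*material entity*); reactions carry process-branch terms
  (biochemical reaction 176, non-covalent binding 177, degradation 179,
  transport 185, generic conversion 182), and degradation's SBO is what
  licenses its empty product list in the validator.

## Annotation

Database dialect normalization is case- and punctuation-insensitive over a
table covering Entrez Gene, OMIM, Ensembl, UniProt, ChEBI, DrugBank, Gene
Ontology, HGNC, PubChem, 3DMET, NCBI Taxonomy, PDBeChem, GlycomeDB,
LipidBank, EC numbers and the KEGG sub-databases, each with the spellings
seen in the wild. Identifiers are percent-encoded into
`urn:miriam:<collection>:<id>` URNs (identifiers.org URL form is available
behind a writer flag). Identifier augmentation is strictly offline: a
user-supplied TSV maps gene symbols to Entrez Gene ids and further
collection ids, standing in for any live lookup service; the resolver is
pluggable, builds and tests never touch the network. Identity links use the
`bqbiol:is` qualifier, complex components `bqbiol:hasPart`, the organism
`bqbiol:occursIn`; annotation is idempotent by construction (the qualifier's
term set is replaced, not appended).

## Synthetic fixtures — what they do and do not show

The fixture module generates one minimal document per entity class, per
decision-table cell, and per pathological case (no Pathway element, entity
reuse across interactions, unknown cross-reference dialect, missing cellular
location, opposing controls, typeless control, multi-compartment transport,
non-unit stoichiometry, zero/two BioSources). Structure is fixed per
scenario; the seed only rotates display names from a fixed gene-symbol list,
so suites are byte-reproducible. These fixtures exercise every mapping rule
and every robustness path the converter claims, but they are *minimal*: they
do not reproduce the scale, the annotation noise, or the deeply nested
participant structures of real database exports, so passing them shows rule
correctness, not corpus-level performance.

## Numerical and identifier conventions

Stoichiometry is held as exact rationals and printed as decimals.
SBML identifiers derive from the URI fragment, rewritten to the SId grammar
(non-alphanumerics → `_`, leading digit prefixed with `_`), with
deterministic `_2`, `_3`, ... suffixes on collision in first-seen order.
Output element order is fixed (compartments, species, reactions, then the
qual lists), empty `listOf` containers are never serialized, and the qual
package is declared with `required="false"` since the transitions carry no
mathematics that alters core semantics.

## Validation

`validate_structure` checks the in-memory document (duplicate ids, dangling
compartment/species/qualitativeSpecies references, participant-free
reactions without a degradation/synthesis SBO, output-free transitions,
sign vocabulary); `validate_sbml_file` re-checks serialized XML and
additionally catches the two serialization-only defects, empty `listOf`
elements and model children out of schema order. The converter's contract is
that every conversion of a generated fixture yields an empty report, which
the test suite asserts across the whole matrix. Full sbml.org
consistency-rule coverage (units, math) is a non-goal.

## Problem sizes

All tests and the acceptance script run on the generated fixture suites
(28 control scenarios, 13 entity scenarios and about twenty edge cases
across both levels, each a document of one to six objects); the complete
suite runs in a few seconds.
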