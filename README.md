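# paxqual

Convert BioPAX Level 2/3 pathway documents into joint SBML Level 3 Version 1
**core + qual** models — translating both *reactions* and *relations*.

## The problem

Pathway databases (the Nature Pathway Interaction Database, BioCarta,
Reactome exports and the like) distribute their content as BioPAX, an
OWL/RDF ontology built for qualitative pathway description. Modeling and
simulation tools speak SBML, whose core vocabulary only knows stoichiometric
reactions. Everything else a signaling pathway contains — enzyme–enzyme
relations, transcription-factor/gene interactions, links between pathways —
is a *relation*, and naive converters either force relations into fake
reactions or silently drop them.

The SBML Level 3 Qualitative Models package (*qual*) closes that gap:
`qualitativeSpecies` carry discrete activity states and `transition`
elements connect signed inputs (`positive`, `negative`, `dual`, `unknown`)
to outputs. `paxqual` emits one joint document per BioPAX file: a core model
(compartments, species, reactions) that legacy tools can read, plus a
qualitative model holding every relation, so no information is lost.

## The translation

Four steps, driven by three mapping tables (`paxqual.tables`):

1. **Initialize** — one core model + one qualitative model for the whole
   file; the pathway organism (from `BioSource`) becomes a
   `urn:miriam:taxonomy:<id>` annotation.
2. **Entities** — every physical entity becomes exactly one `species` *and*
   one `qualitativeSpecies`, SBO-termed by class
   (Protein → SBO:0000252 polypeptide chain, Complex → SBO:0000253,
   Gene → SBO:0000354, DNA/DnaRegion → SBO:0000251, RNA/RnaRegion →
   SBO:0000250, SmallMolecule → SBO:0000247), placed in the compartment
   derived from its cellular location (or the default compartment).
3. **Interactions** — every Conversion (biochemical reaction, complex
   assembly, transport, degradation) becomes a reaction preserving
   stoichiometry. A Control becomes either a reaction **modifier** or a qual
   **transition**, decided by the (Controller kind, Controlled kind) pair —
   e.g. a physical entity catalysing a biochemical reaction stays in the
   core model, while anything controlled by or controlling a pathway, a
   template reaction or a generic conversion becomes a transition. The
   `controlType` sets the input sign (ACTIVATION\* → positive,
   INHIBITION\* → negative, unspecified → unknown); opposing controls on
   the same input/output pair merge to `dual`.
4. **Annotate** — cross-reference database dialects ("UniProt",
   "UniProtKB", ...) are normalized to MIRIAM collections and emitted as
   `urn:miriam:<collection>:<id>` CV terms; an offline TSV mapping table can
   augment species with Entrez Gene and further identifiers (no network is
   ever touched).

Conversion is deterministic: the same input always yields byte-identical
SBML. A structural validator (`paxqual.sbml.validate_structure` /
`validate_sbml_file`) checks the guarantees the converter makes: no
undeclared species references, no duplicate identifiers, no empty `listOf`
elements, schema element order, well-formed signs.

## Worked example

A protein (ERK2) inhibiting an apoptosis pathway — the smallest document
that needs the qual package:

```python
from paxqual import *

doc = BioPaxDocument(
    level=3,
    entities=[BioPaxEntity(uri="#erk", entity_class=EntityClass.PROTEIN,
                           display_name="MAPK1",
                           cellular_location="cytoplasm",
                           xrefs=[Xref("UniProtKB", "P28482"),
                                  Xref("Entrez Gene", "5594")])],
    pathways=[BioPaxPathway(uri="#apoptosis", display_name="Apoptosis")],
    interactions=[BioPaxInteraction(uri="#ctl", kind=InteractionKind.CONTROL,
                                    controllers=["#erk"],
                                    controlled="#apoptosis",
                                    control_type="INHIBITION")],
)
sbml = convert(doc)
print("species:", [(s.id, s.compartment, s.sbo_term) for s in sbml.species])
print("qualitativeSpecies:", [q.id for q in sbml.qual_species])
print("transition inputs:", sbml.transitions[0].inputs)
print("transition outputs:", sbml.transitions[0].outputs)
print("annotations:", [u for t in sbml.species[0].cv_terms for u in t.urns])
print("validation:", validate_structure(sbml))
```

prints

```
species: [('erk', 'cytoplasm', 252)]
qualitativeSpecies: ['q_erk', 'apoptosis']
transition inputs: [('q_erk', <Sign.NEGATIVE: 'negative'>)]
transition outputs: ['apoptosis']
annotations: ['urn:miriam:entrez.gene:5594', 'urn:miriam:uniprot:P28482']
validation: no structural issues
```

The protein yields one species (SBO:0000252, in the `cytoplasm`
compartment) and one qualitativeSpecies; the pathway is represented on the
qualitative side by a proxy qualitativeSpecies; the inhibition becomes a
transition whose input sign is `negative`. `write_sbml(sbml, "out.xml")`
serializes the joint document.

The same pipeline is available from the shell:

```sh
paxqual fixtures --level 3 -o fixtures/      # generate conformance inputs
paxqual convert fixtures/*.owl -o converted/
paxqual validate converted/entity-protein_L3.sbml.xml
```

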