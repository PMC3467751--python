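"""Programmatic generation of minimal, valid BioPAX test documents.

Every entity class and every (controller, controlled) decision-table cell has
a scenario here, plus the pathological cases a robust converter must survive:
a file without any Pathway element, an entity reused across interactions, an
unrecognized cross-reference database, a missing cellular location.  Keeping
the fixtures generated (rather than checked in) keeps the conformance matrix
in one place and automatically in sync with the mapping tables.

Structure is fixed per scenario; the seed only rotates which names are drawn
from a fixed gene-symbol list, so two calls with the same seed are
byte-identical after serialization.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

from .biopax_io import write_biopax
from .model import (
    BioPaxDocument,
    BioPaxEntity,
    BioPaxInteraction,
    BioPaxPathway,
    BioSource,
    EntityClass,
    InteractionKind,
    Participant,
    Xref,
)
from .tables import DECISION

BASE = "http://paxqual.org/fixture#"

_SYMBOLS = ["TP53", "MDM2", "EGFR", "AKT1", "KRAS", "MYC", "BRCA1", "CDK2"]


class InconsistentSpecError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    scenario: str
    level: int = 3
    seed: int = 0


# --- scenario catalogue -----------------------------------------------------

ENTITY_SCENARIOS: dict[str, EntityClass] = {
    "entity-gene": EntityClass.GENE,
    "entity-complex": EntityClass.COMPLEX,
    "entity-protein": EntityClass.PROTEIN,
    "entity-dna": EntityClass.DNA,
    "entity-dna-region": EntityClass.DNA_REGION,
    "entity-rna": EntityClass.RNA,
    "entity-rna-region": EntityClass.RNA_REGION,
    "entity-small-molecule": EntityClass.SMALL_MOLECULE,
}
_L3_ONLY_ENTITY_SCENARIOS = {"entity-gene", "entity-dna-region",
                             "entity-rna-region"}

EDGE_SCENARIOS = [
    "no-pathway-element",
    "duplicate-entity-use",
    "unknown-xref-dialect",
    "missing-cellular-location",
    "stoichiometric-reaction",
    "transport-two-compartments",
    "opposing-controls",
    "typeless-control",
    "organism",
    "two-biosources",
]
_L3_ONLY_EDGE_SCENARIOS = {"degradation-standalone"}
EDGE_SCENARIOS_L3 = EDGE_SCENARIOS + ["degradation-standalone"]


def control_scenarios(level: int) -> dict[str, tuple[str, str]]:
    """scenario name -> (controller kind, controlled decision-table token),
    derived from the decision table so coverage cannot drift."""
    out = {}
    for (ctl, token, lv) in DECISION:
        if lv != level:
            continue
        prefix = "pe" if ctl == "physical_entity" else "pathway"
        out[f"{prefix}-controls-{token.lower()}"] = (ctl, token)
    return out


def scenario_names(level: int) -> list[str]:
    names = [s for s in ENTITY_SCENARIOS
             if level == 3 or s not in _L3_ONLY_ENTITY_SCENARIOS]
    names += sorted(control_scenarios(level))
    names += EDGE_SCENARIOS_L3 if level == 3 else EDGE_SCENARIOS
    return names


# --- builders ---------------------------------------------------------------


class _Builder:
    def __init__(self, spec: FixtureSpec):
        self.spec = spec
        self.entities: list[BioPaxEntity] = []
        self.interactions: list[BioPaxInteraction] = []
        self.pathways: list[BioPaxPathway] = []
        self.bio_sources: list[BioSource] = []
        self._n = 0

    def name(self) -> str:
        value = _SYMBOLS[(self.spec.seed + self._n) % len(_SYMBOLS)]
        self._n += 1
        return value

    def protein(self, uri: str, location: str | None = "cytoplasm",
                xrefs: list[Xref] | None = None,
                cls: EntityClass = EntityClass.PROTEIN,
                components: list[str] | None = None) -> BioPaxEntity:
        ent = BioPaxEntity(
            uri=BASE + uri, entity_class=cls, display_name=self.name(),
            cellular_location=location, xrefs=xrefs or [],
            component_refs=[BASE + c for c in (components or [])],
        )
        self.entities.append(ent)
        return ent

    def interaction(self, uri: str, kind: InteractionKind, *,
                    left=(), right=(), controllers=(), controlled=None,
                    control_type=None) -> BioPaxInteraction:
        ia = BioPaxInteraction(
            uri=BASE + uri, kind=kind,
            left=[p if isinstance(p, Participant)
                  else Participant(BASE + p) for p in left],
            right=[p if isinstance(p, Participant)
                   else Participant(BASE + p) for p in right],
            controllers=[BASE + c for c in controllers],
            controlled=BASE + controlled if controlled else None,
            control_type=control_type,
        )
        self.interactions.append(ia)
        return ia

    def pathway(self, uri: str, components=()) -> BioPaxPathway:
        pw = BioPaxPathway(
            uri=BASE + uri, display_name=f"{self.name()} pathway",
            component_interaction_refs=[BASE + c for c in components],
        )
        self.pathways.append(pw)
        return pw

    def doc(self) -> BioPaxDocument:
        return BioPaxDocument(
            level=self.spec.level,
            entities=self.entities,
            interactions=self.interactions,
            pathways=self.pathways,
            bio_sources=self.bio_sources,
            source_uri=f"fixture:{self.spec.scenario}",
        )

    # controlled-interaction templates, one per decision-table token

    def controlled_interaction(self, token: str) -> str:
        """Build the interaction (or pathway) a control scenario targets;
        returns its URI fragment."""
        t = token.lower()
        if t == "pathway":
            self.pathway("target_pw")
            return "target_pw"
        if t == "biochemicalreaction":
            self.protein("sub")
            self.protein("prod")
            self.interaction("target", InteractionKind.BIOCHEMICAL_REACTION,
                             left=["sub"], right=["prod"])
        elif t == "complexassembly":
            self.protein("sub")
            self.protein("sub2")
            self.protein("cplx", cls=EntityClass.COMPLEX,
                         components=["sub", "sub2"])
            self.interaction("target", InteractionKind.COMPLEX_ASSEMBLY,
                             left=["sub", "sub2"], right=["cplx"])
        elif t == "conversion":
            self.protein("sub")
            self.protein("prod")
            self.interaction("target", InteractionKind.GENERIC_CONVERSION,
                             left=["sub"], right=["prod"])
        elif t == "interaction":
            self.protein("prod")
            self.interaction("target", InteractionKind.GENERIC_INTERACTION,
                             right=["prod"])
        elif t == "degradation":
            self.protein("sub")
            self.interaction("target", InteractionKind.DEGRADATION,
                             left=["sub"])
        elif t == "transport":
            self.protein("cargo_cyt", location="cytoplasm")
            self.protein("cargo_nuc", location="nucleus")
            self.interaction("target", InteractionKind.TRANSPORT,
                             left=["cargo_cyt"], right=["cargo_nuc"])
        elif t == "transportwithbiochemicalreaction":
            self.protein("cargo_cyt", location="cytoplasm")
            self.protein("cargo_nuc", location="nucleus")
            self.interaction(
                "target",
                InteractionKind.TRANSPORT_WITH_BIOCHEMICAL_REACTION,
                left=[Participant(BASE + "cargo_cyt", Fraction(2))],
                right=[Participant(BASE + "cargo_nuc", Fraction(2))])
        elif t == "templatereaction":
            self.protein("template", cls=EntityClass.GENE, location=None)
            self.protein("prod")
            self.interaction("target", InteractionKind.TEMPLATE_REACTION,
                             left=["template"], right=["prod"])
        else:  # pragma: no cover - catalogue and builders kept in sync
            raise InconsistentSpecError(f"no builder for token {token!r}")
        return "target"


def generate_fixture(spec: FixtureSpec) -> BioPaxDocument:
    """Build the in-memory BioPAX document for one scenario."""
    if spec.level not in (2, 3):
        raise InconsistentSpecError(f"level must be 2 or 3: {spec.level}")
    scenario = spec.scenario
    if scenario not in scenario_names(spec.level):
        if scenario in scenario_names(2) + scenario_names(3):
            raise InconsistentSpecError(
                f"scenario {scenario!r} not available at level {spec.level}")
        raise InconsistentSpecError(f"unknown scenario {scenario!r}")

    b = _Builder(spec)

    if scenario in ENTITY_SCENARIOS:
        cls = ENTITY_SCENARIOS[scenario]
        if cls is EntityClass.COMPLEX:
            b.protein("comp_a", xrefs=[Xref("UniProt", "P04637")])
            b.protein("comp_b", xrefs=[Xref("UniProtKB", "Q00987")])
            b.protein("cplx", cls=cls, components=["comp_a", "comp_b"])
        else:
            b.protein("ent", cls=cls,
                      xrefs=[Xref("Entrez Gene", "7157"),
                             Xref("UniProt", "P04637")])
        return b.doc()

    controls = control_scenarios(spec.level)
    if scenario in controls:
        ctl_kind, token = controls[scenario]
        target = b.controlled_interaction(token)
        if ctl_kind == "physical_entity":
            b.protein("ctl")
            controller = "ctl"
        else:
            b.pathway("ctl_pw")
            controller = "ctl_pw"
        kind = (InteractionKind.CATALYSIS
                if token.lower() == "biochemicalreaction"
                and ctl_kind == "physical_entity"
                else InteractionKind.CONTROL)
        b.interaction("control", kind, controllers=[controller],
                      controlled=target, control_type="ACTIVATION")
        return b.doc()

    if scenario == "no-pathway-element":
        b.protein("a")
        b.protein("b")
        b.interaction("rx", InteractionKind.BIOCHEMICAL_REACTION,
                      left=["a"], right=["b"])
    elif scenario == "duplicate-entity-use":
        b.protein("shared")
        b.protein("out1")
        b.protein("out2")
        b.interaction("rx1", InteractionKind.BIOCHEMICAL_REACTION,
                      left=["shared"], right=["out1"])
        b.interaction("rx2", InteractionKind.BIOCHEMICAL_REACTION,
                      left=["shared"], right=["out2"])
    elif scenario == "unknown-xref-dialect":
        b.protein("ent", xrefs=[Xref("MadeUpDB", "x1"),
                                Xref("uniprot", "P04637")])
    elif scenario == "missing-cellular-location":
        b.protein("ent", location=None)
    elif scenario == "stoichiometric-reaction":
        b.protein("a", cls=EntityClass.SMALL_MOLECULE)
        b.protein("bb", cls=EntityClass.SMALL_MOLECULE)
        b.protein("c", cls=EntityClass.SMALL_MOLECULE)
        b.interaction("rx", InteractionKind.BIOCHEMICAL_REACTION,
                      left=[Participant(BASE + "a"),
                            Participant(BASE + "bb", Fraction(2))],
                      right=[Participant(BASE + "c")])
    elif scenario == "transport-two-compartments":
        b.protein("x_cyt", location="cytoplasm")
        b.protein("x_nuc", location="nucleus")
        b.interaction("rx", InteractionKind.TRANSPORT,
                      left=["x_cyt"], right=["x_nuc"])
    elif scenario == "degradation-standalone":
        b.protein("doomed")
        b.interaction("rx", InteractionKind.DEGRADATION, left=["doomed"])
    elif scenario == "opposing-controls":
        if spec.level == 3:
            b.protein("template", cls=EntityClass.GENE, location=None)
            b.protein("prod")
            b.interaction("target", InteractionKind.TEMPLATE_REACTION,
                          left=["template"], right=["prod"])
        else:
            b.protein("prod")
            b.interaction("target", InteractionKind.GENERIC_INTERACTION,
                          right=["prod"])
        b.protein("ctl")
        b.interaction("act", InteractionKind.CONTROL, controllers=["ctl"],
                      controlled="target", control_type="ACTIVATION")
        b.interaction("inh", InteractionKind.CONTROL, controllers=["ctl"],
                      controlled="target", control_type="INHIBITION")
    elif scenario == "typeless-control":
        b.protein("ctl")
        b.pathway("target_pw")
        b.interaction("control", InteractionKind.CONTROL,
                      controllers=["ctl"], controlled="target_pw")
    elif scenario == "organism":
        b.protein("a")
        b.protein("b")
        b.interaction("rx", InteractionKind.BIOCHEMICAL_REACTION,
                      left=["a"], right=["b"])
        b.pathway("pw", components=["rx"])
        b.bio_sources.append(BioSource(name="Homo sapiens",
                                       taxonomy_id="9606"))
    elif scenario == "two-biosources":
        b.protein("a")
        b.pathway("pw")
        b.bio_sources.append(BioSource(name="Homo sapiens",
                                       taxonomy_id="9606"))
        b.bio_sources.append(BioSource(name="Mus musculus",
                                       taxonomy_id="10090"))
    else:  # pragma: no cover
        raise InconsistentSpecError(f"unknown scenario {scenario!r}")
    return b.doc()


def generate_suite(level: int, out_dir: str | Path,
                   seed: int = 0) -> list[Path]:
    """Write one BioPAX file per scenario applicable at this level."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for scenario in scenario_names(level):
        doc = generate_fixture(FixtureSpec(scenario, level, seed))
        path = out_dir / f"{scenario}_L{level}.owl"
        write_biopax(doc, path)
        paths.append(path)
    return paths
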