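"""Deterministic example ontologies, profiles and synthetic corpora.

Two hand-built fixture ontologies anchor all worked examples:

* a cell-part ontology (CPH prefix) around the epithelial /
  mesenchymal / embryonic-stem-cell phenotypes, with the tight junction
  and its necessary molecular parts (Occludin, JAM, Claudin);
* a cell-mechanism ontology (CMM prefix) with the networks of
  mechanisms relevant for those cells, junction-formation events, and
  molecular interactions such as Occludin-JAM, plus the mitosis /
  S-phase temporal-part example.

Both encode only structure stated for the running examples; a few glue
terms (the adherens-junction molecules, a cytoskeletal branch, a cell
cycle interaction) are invented here so that transition rules can fire
at every step of the example time series and so the synthetic corpus
has three disjoint prototype regions.  The synthetic generator plants
cluster structure by perturbing per-cluster prototype profiles with
annotation dropout, granularity shifts along the propagation order
(emulating curation at mixed coarseness) and random spurious additions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .onto import (
    HAS_PART,
    IS_A,
    MECHANISM,
    MECHANISM_CATEGORIES,
    PHENOTYPE,
    PHENOTYPE_CATEGORIES,
    Edge,
    Ontology,
    Term,
)
from .profiles import (
    DEFAULT_VOCABULARY,
    MECHANISM_CHANGE_KIND,
    PHENOTYPE_KIND,
    AnnotationProfile,
    Corpus,
    EQAnnotation,
    ProfileSeries,
    QualityVocabulary,
    profile,
)
from .transitions import MarkerRule, MechanismMap, ParticipantRule

# ---------------------------------------------------------------------
# cell-part ontology (CPH)
# ---------------------------------------------------------------------

PHEN = {
    "Epithelial cell": "CPH:0000001",
    "Mesenchymal cell": "CPH:0000002",
    "Embryonic stem cell": "CPH:0000003",
    "Cell membrane": "CPH:0000004",
    "Cell junction": "CPH:0000005",
    "Tight junction": "CPH:0000006",
    "Adherens junction": "CPH:0000007",
    "Occludin": "CPH:0000008",
    "JAM": "CPH:0000009",
    "Claudin": "CPH:0000010",
    "E-cadherin": "CPH:0000011",
    "Beta-catenin": "CPH:0000012",
    "Vimentin": "CPH:0000013",
}

_PHEN_CATEGORIES = {
    "Epithelial cell": "cell",
    "Mesenchymal cell": "cell",
    "Embryonic stem cell": "cell",
    "Cell membrane": "structure",
    "Cell junction": "ultrastructure",
    "Tight junction": "ultrastructure",
    "Adherens junction": "ultrastructure",
    "Occludin": "molecule",
    "JAM": "molecule",
    "Claudin": "molecule",
    "E-cadherin": "molecule",
    "Beta-catenin": "molecule",
    "Vimentin": "molecule",
}


def build_phenotype_fixture() -> Ontology:
    """The example ontology of cell parts; deterministic ids and edges."""
    terms = [Term(id=PHEN[name], label=name, category=_PHEN_CATEGORIES[name])
             for name in PHEN]
    P = PHEN
    edges = [
        Edge(P["Tight junction"], IS_A, P["Cell junction"]),
        Edge(P["Adherens junction"], IS_A, P["Cell junction"]),
        # the tight junction necessitates its molecular parts
        Edge(P["Tight junction"], HAS_PART, P["Occludin"]),
        Edge(P["Tight junction"], HAS_PART, P["JAM"]),
        Edge(P["Tight junction"], HAS_PART, P["Claudin"]),
        Edge(P["Epithelial cell"], HAS_PART, P["Tight junction"]),
        Edge(P["Epithelial cell"], HAS_PART, P["Cell membrane"]),
        # invented glue: adherens-junction molecular parts and the
        # mesenchymal membrane/intermediate-filament branch
        Edge(P["Epithelial cell"], HAS_PART, P["Adherens junction"]),
        Edge(P["Adherens junction"], HAS_PART, P["E-cadherin"]),
        Edge(P["Adherens junction"], HAS_PART, P["Beta-catenin"]),
        Edge(P["Mesenchymal cell"], HAS_PART, P["Cell membrane"]),
        Edge(P["Mesenchymal cell"], HAS_PART, P["Vimentin"]),
        Edge(P["Embryonic stem cell"], HAS_PART, P["Cell membrane"]),
    ]
    return Ontology(PHENOTYPE, terms, edges)


# ---------------------------------------------------------------------
# cell-mechanism ontology (CMM)
# ---------------------------------------------------------------------

MECH = {
    "Network for epithelial cell": "CMM:0000001",
    "Network for mesenchymal cell": "CMM:0000002",
    "Network for tight junction": "CMM:0000003",
    "TJ formation": "CMM:0000004",
    "AJ formation": "CMM:0000005",
    "Interaction Occludin-JAM": "CMM:0000006",
    "Mitosis": "CMM:0000007",
    "S-phase": "CMM:0000008",
    "Interaction E-cadherin-Beta-catenin": "CMM:0000009",
    "Cytoskeletal remodelling": "CMM:0000010",
    "Interaction Vimentin-Vimentin": "CMM:0000011",
    "Interaction CDK1-CyclinB": "CMM:0000012",
}

_MECH_CATEGORIES = {
    "Network for epithelial cell": "mechanism-network",
    "Network for mesenchymal cell": "mechanism-network",
    "Network for tight junction": "mechanism-network",
    "TJ formation": "ultrastructural-event",
    "AJ formation": "ultrastructural-event",
    "Interaction Occludin-JAM": "molecular-interaction",
    "Mitosis": "ultrastructural-event",
    "S-phase": "ultrastructural-event",
    "Interaction E-cadherin-Beta-catenin": "molecular-interaction",
    "Cytoskeletal remodelling": "ultrastructural-event",
    "Interaction Vimentin-Vimentin": "molecular-interaction",
    "Interaction CDK1-CyclinB": "molecular-interaction",
}


def build_mechanism_fixture() -> Ontology:
    """The example ontology of cell mechanisms (occurrents)."""
    terms = [Term(id=MECH[name], label=name, category=_MECH_CATEGORIES[name])
             for name in MECH]
    M = MECH
    edges = [
        # the epithelial programme necessitates junction formation
        Edge(M["Network for epithelial cell"], HAS_PART, M["Network for tight junction"]),
        Edge(M["Network for epithelial cell"], HAS_PART, M["AJ formation"]),
        Edge(M["Network for tight junction"], HAS_PART, M["Interaction Occludin-JAM"]),
        # TJ formation is the start-up of the TJ-relevant mechanisms
        Edge(M["TJ formation"], HAS_PART, M["Network for tight junction"]),
        # every mitosis has an S-phase as a temporal part
        Edge(M["Mitosis"], HAS_PART, M["S-phase"]),
        # invented glue branches (adherens, cytoskeleton, cell cycle)
        Edge(M["AJ formation"], HAS_PART, M["Interaction E-cadherin-Beta-catenin"]),
        Edge(M["Network for mesenchymal cell"], HAS_PART, M["Cytoskeletal remodelling"]),
        Edge(M["Cytoskeletal remodelling"], HAS_PART, M["Interaction Vimentin-Vimentin"]),
        Edge(M["Mitosis"], HAS_PART, M["Interaction CDK1-CyclinB"]),
    ]
    return Ontology(MECHANISM, terms, edges)


# ---------------------------------------------------------------------
# worked-example profiles
# ---------------------------------------------------------------------

def build_epithelial_profile(vocab: QualityVocabulary = DEFAULT_VOCABULARY) -> AnnotationProfile:
    """The epithelial phenotype: Occludin, JAM, Claudin and TJs present,
    cell membranes joined."""
    return profile("epithelial", PHENOTYPE_KIND, [
        (PHEN["Occludin"], "present"),
        (PHEN["JAM"], "present"),
        (PHEN["Claudin"], "present"),
        (PHEN["Tight junction"], "present"),
        (PHEN["Cell membrane"], "joined"),
    ], vocab=vocab)


def build_met_marker_pair() -> tuple[AnnotationProfile, AnnotationProfile, MechanismMap]:
    """Mesenchymal -> epithelial phenotype pair plus the marker-only map
    under which the derived transition is exactly
    {(Network for epithelial cell, up), (Network for mesenchymal cell, down)}."""
    a = profile("mesenchymal-state", PHENOTYPE_KIND, [
        (PHEN["Epithelial cell"], "absent"),
        (PHEN["Mesenchymal cell"], "present"),
    ])
    b = profile("epithelial-state", PHENOTYPE_KIND, [
        (PHEN["Epithelial cell"], "present"),
        (PHEN["Mesenchymal cell"], "absent"),
    ])
    m = MechanismMap(
        markers=(
            MarkerRule(PHEN["Epithelial cell"], MECH["Network for epithelial cell"]),
            MarkerRule(PHEN["Mesenchymal cell"], MECH["Network for mesenchymal cell"]),
        ),
        participants=(),
    )
    return a, b, m


def build_fixture_mechanism_map() -> MechanismMap:
    """The full example bridge between the two fixture ontologies."""
    return MechanismMap(
        markers=(
            MarkerRule(PHEN["Epithelial cell"], MECH["Network for epithelial cell"]),
            MarkerRule(PHEN["Mesenchymal cell"], MECH["Network for mesenchymal cell"]),
            MarkerRule(PHEN["Tight junction"], MECH["Network for tight junction"]),
            MarkerRule(PHEN["Adherens junction"], MECH["AJ formation"]),
        ),
        participants=(
            ParticipantRule(MECH["Interaction Occludin-JAM"],
                            frozenset({PHEN["Occludin"], PHEN["JAM"]})),
            ParticipantRule(MECH["Interaction E-cadherin-Beta-catenin"],
                            frozenset({PHEN["E-cadherin"], PHEN["Beta-catenin"]})),
        ),
    )


def build_figure3_series() -> tuple[ProfileSeries, MechanismMap]:
    """A three-point MET time course: A before intervention, B at 1 h
    (adherens junctions formed), C at 2 h (tight junctions formed).

    Each consecutive pair triggers at least one marker and one
    participant rule of the accompanying mechanism map.  The exact
    annotation contents are this package's convention; only the
    timestamps and the three-profile structure are fixed by the example.
    """
    a = profile("cell-A", PHENOTYPE_KIND, [
        (PHEN["Mesenchymal cell"], "present"),
        (PHEN["Epithelial cell"], "absent"),
        (PHEN["Vimentin"], "present"),
        (PHEN["Adherens junction"], "absent"),
        (PHEN["E-cadherin"], "absent"),
        (PHEN["Beta-catenin"], "present"),
        (PHEN["Tight junction"], "absent"),
        (PHEN["Occludin"], "absent"),
        (PHEN["JAM"], "present"),
        (PHEN["Claudin"], "absent"),
    ], timestamp=None)
    b = profile("cell-B", PHENOTYPE_KIND, [
        (PHEN["Mesenchymal cell"], "absent"),
        (PHEN["Epithelial cell"], "absent"),
        (PHEN["Vimentin"], "present"),
        (PHEN["Adherens junction"], "present"),
        (PHEN["E-cadherin"], "present"),
        (PHEN["Beta-catenin"], "present"),
        (PHEN["Tight junction"], "absent"),
        (PHEN["Occludin"], "absent"),
        (PHEN["JAM"], "present"),
        (PHEN["Claudin"], "present"),
    ], timestamp=1.0)
    c = profile("cell-C", PHENOTYPE_KIND, [
        (PHEN["Mesenchymal cell"], "absent"),
        (PHEN["Epithelial cell"], "present"),
        (PHEN["Vimentin"], "absent"),
        (PHEN["Adherens junction"], "present"),
        (PHEN["E-cadherin"], "present"),
        (PHEN["Beta-catenin"], "present"),
        (PHEN["Tight junction"], "present"),
        (PHEN["Occludin"], "present"),
        (PHEN["JAM"], "present"),
        (PHEN["Claudin"], "present"),
    ], timestamp=2.0)
    return ProfileSeries((a, b, c)), build_fixture_mechanism_map()


def build_figure4_profiles() -> Corpus:
    """MET mechanism-change profiles curated at three granularities, plus
    an unrelated mesenchymal shutdown control.

    Before propagation the three MET profiles assert disjoint sets; after
    propagation all three share (Interaction Occludin-JAM, up).
    """
    met_network = profile("met-network", MECHANISM_CHANGE_KIND, [
        (MECH["Network for epithelial cell"], "up"),
    ])
    met_event = profile("met-event", MECHANISM_CHANGE_KIND, [
        (MECH["Network for tight junction"], "up"),
        (MECH["AJ formation"], "up"),
    ])
    met_interaction = profile("met-interaction", MECHANISM_CHANGE_KIND, [
        (MECH["Interaction Occludin-JAM"], "up"),
    ])
    control = profile("control-mesenchymal", MECHANISM_CHANGE_KIND, [
        (MECH["Network for mesenchymal cell"], "down"),
    ])
    return Corpus((met_network, met_event, met_interaction, control))


MET_PROFILE_IDS = ("met-network", "met-event", "met-interaction")


# ---------------------------------------------------------------------
# synthetic corpora with planted clusters
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions for the planted-cluster corpus generator.

    ``dropout`` is the per-annotation drop probability (and the
    probability of one spurious added annotation); ``granularity_shift``
    is the probability that a surviving annotation is re-curated onto a
    uniformly chosen member of its positive scope, emulating curation at
    mixed coarseness.
    """

    ontology: Ontology
    prototypes: tuple[AnnotationProfile, ...]
    profiles_per_cluster: int = 10
    dropout: float = 0.1
    granularity_shift: float = 0.3
    seed: int = 42

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if not 0.0 <= self.granularity_shift < 1.0:
            raise ValueError("granularity_shift must lie in [0, 1)")
        if not self.prototypes:
            raise ValueError("at least one prototype profile is required")
        if self.profiles_per_cluster < 1:
            raise ValueError("profiles_per_cluster must be positive")


def default_synthetic_spec(seed: int = 42) -> SyntheticSpec:
    """Three mechanism-change prototype programmes over disjoint regions
    of the mechanism fixture: MET start-up, a mesenchymal/cytoskeletal
    programme, and the cell-cycle branch."""
    met = profile("proto-met", MECHANISM_CHANGE_KIND, [
        (MECH["Network for epithelial cell"], "up"),
        (MECH["Network for tight junction"], "up"),
        (MECH["AJ formation"], "up"),
        (MECH["Interaction Occludin-JAM"], "up"),
    ])
    mesenchymal = profile("proto-mesenchymal", MECHANISM_CHANGE_KIND, [
        (MECH["Network for mesenchymal cell"], "up"),
        (MECH["Cytoskeletal remodelling"], "up"),
        (MECH["Interaction Vimentin-Vimentin"], "up"),
    ])
    cycle = profile("proto-cycle", MECHANISM_CHANGE_KIND, [
        (MECH["Mitosis"], "up"),
        (MECH["S-phase"], "up"),
        (MECH["Interaction CDK1-CyclinB"], "up"),
    ])
    return SyntheticSpec(ontology=build_mechanism_fixture(),
                         prototypes=(met, mesenchymal, cycle), seed=seed)


def generate_synthetic_corpus(spec: SyntheticSpec,
                              vocab: QualityVocabulary = DEFAULT_VOCABULARY
                              ) -> tuple[Corpus, dict[str, int]]:
    """Planted-cluster corpus: perturbed copies of each prototype.

    Per profile: each prototype annotation is dropped with probability
    ``dropout``; each survivor is, with probability ``granularity_shift``,
    re-annotated onto a uniformly chosen unused member of its positive
    scope; finally, with probability ``dropout``, one spurious annotation
    on a uniformly chosen unused ontology term (quality drawn from the
    prototype) is added.  Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    o = spec.ontology
    all_terms = sorted(o.terms)
    profiles: list[AnnotationProfile] = []
    labels: dict[str, int] = {}
    for ci, proto in enumerate(spec.prototypes):
        proto_anns = sorted(proto.annotations, key=lambda a: (a.entity, a.quality.name))
        for j in range(spec.profiles_per_cluster):
            kept = [a for a in proto_anns if rng.random() >= spec.dropout]
            chosen: dict[str, EQAnnotation] = {}
            for a in kept:
                entity = a.entity
                if rng.random() < spec.granularity_shift:
                    scope = sorted(o.positive_scope(a.entity))
                    entity = scope[int(rng.integers(len(scope)))]
                # shifted annotations may collide; duplicates merge, and a
                # would-be polarity conflict keeps the first arrival
                if entity not in chosen:
                    chosen[entity] = EQAnnotation(entity, a.quality)
            if rng.random() < spec.dropout and proto_anns:
                free = [t for t in all_terms if t not in chosen]
                if free:
                    entity = free[int(rng.integers(len(free)))]
                    quality = proto_anns[int(rng.integers(len(proto_anns)))].quality
                    chosen[entity] = EQAnnotation(entity, quality)
            pid = f"{proto.id}-{j:02d}"
            profiles.append(AnnotationProfile(
                id=pid, kind=proto.kind, annotations=frozenset(chosen.values()),
                timestamp=proto.timestamp))
            labels[pid] = ci + 1
    return Corpus(tuple(profiles)), labels


# ---------------------------------------------------------------------
# seeded random instances (round-trip and oracle exercises)
# ---------------------------------------------------------------------

def random_ontology(rng: np.random.Generator, n_terms: int = 20,
                    kind: str = PHENOTYPE, edge_prob: float = 0.15) -> Ontology:
    """A random per-relation-acyclic ontology (edges respect id order)."""
    prefix = "CPH" if kind == PHENOTYPE else "CMM"
    cats = PHENOTYPE_CATEGORIES if kind == PHENOTYPE else MECHANISM_CATEGORIES
    terms = [
        Term(id=f"{prefix}:{i:07d}", label=f"random term {i}",
             category=cats[int(rng.integers(len(cats)))])
        for i in range(1, n_terms + 1)
    ]
    edges = []
    for i in range(n_terms):
        for j in range(i + 1, n_terms):
            if rng.random() < edge_prob:
                rel = IS_A if rng.random() < 0.5 else HAS_PART
                edges.append(Edge(terms[i].id, rel, terms[j].id))
    return Ontology(kind, terms, edges)


def random_corpus(rng: np.random.Generator, o: Ontology, n_profiles: int = 8,
                  kind: str = MECHANISM_CHANGE_KIND, positive_only: bool = True,
                  max_annotations: int = 5,
                  vocab: QualityVocabulary = DEFAULT_VOCABULARY) -> Corpus:
    """Random valid profiles over ``o`` (positive-only by default)."""
    if positive_only:
        pool = [q for q in vocab.allowed_for(kind)
                if vocab.quality(q).polarity == "positive"]
    else:
        pool = list(vocab.allowed_for(kind))
    term_ids = sorted(o.terms)
    profiles = []
    for i in range(n_profiles):
        n_ann = int(rng.integers(1, max_annotations + 1))
        entities = rng.choice(term_ids, size=min(n_ann, len(term_ids)), replace=False)
        pairs = [(str(e), pool[int(rng.integers(len(pool)))]) for e in entities]
        profiles.append(profile(f"rnd-{i:03d}", kind, pairs, vocab=vocab))
    return Corpus(tuple(profiles))
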