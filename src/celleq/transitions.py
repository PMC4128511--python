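"""Deriving mechanism-change profiles from pairs of phenotype profiles.

A cell transition (e.g. a mesenchymal-epithelial transition) is an
occurrent: it cannot be read off a single snapshot, but it can be
derived by *differential analysis* of two time-stamped phenotype
profiles.  The bridge between the two ontologies is an explicit
:class:`MechanismMap`:

* marker rules — a phenotype structure/cell term whose appearance or
  disappearance marks the start-up / shutdown of a mechanism term
  (e.g. Tight junction -> Network of mechanisms relevant for TJ);
* participant rules — a molecular interaction together with its
  participant molecules; the interaction starts up when all participants
  become jointly present, and shuts down when one is lost.

Annotation is open-world: an entity not mentioned in a profile is
unknown, not absent, and contributes nothing.  The derived transition
inherits its start/end timestamps from the two phenotype profiles.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

from .onto import Ontology, Violation
from .profiles import (
    DEFAULT_VOCABULARY,
    MECHANISM_CHANGE_KIND,
    PHENOTYPE_KIND,
    AnnotationProfile,
    EQAnnotation,
    ProfileSeries,
    QualityVocabulary,
)

#: categories a marker rule may target / a participant rule may source
_MARKER_TARGET_CATEGORIES = ("mechanism-network", "ultrastructural-event")
_PARTICIPANT_SOURCE_CATEGORY = "molecular-interaction"


@dataclass(frozen=True)
class MarkerRule:
    """phenotype structure/cell term -> mechanism term it marks."""

    phenotype: str
    mechanism: str


@dataclass(frozen=True)
class ParticipantRule:
    """mechanism interaction term <- its participant molecule terms."""

    mechanism: str
    participants: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "participants", frozenset(self.participants))


@dataclass(frozen=True)
class MechanismMap:
    markers: tuple[MarkerRule, ...]
    participants: tuple[ParticipantRule, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "markers", tuple(self.markers))
        object.__setattr__(self, "participants", tuple(self.participants))


@dataclass(frozen=True)
class TransitionProfile:
    """A mechanism-change profile with inherited start/end timestamps."""

    profile: AnnotationProfile
    start_h: float | None
    end_h: float | None

    def __post_init__(self) -> None:
        if self.profile.kind != MECHANISM_CHANGE_KIND:
            raise ValueError("transition profile must wrap a mechanism-change profile")
        if self.start_h is not None and self.end_h is not None and not self.end_h > self.start_h:
            raise ValueError(f"end_h ({self.end_h}) must exceed start_h ({self.start_h})")


def validate_mechanism_map(m: MechanismMap, op: Ontology, om: Ontology) -> list[Violation]:
    """Dangling ids, wrong-category rule endpoints, undersized participant sets."""
    violations: list[Violation] = []
    if op.kind != "phenotype" or om.kind != "mechanism":
        violations.append(Violation(
            "ontology-kind", "map must bridge a phenotype and a mechanism ontology", ()))
        return violations
    for r in m.markers:
        if r.phenotype not in op:
            violations.append(Violation(
                "dangling-id", f"marker source {r.phenotype} not in phenotype ontology",
                (r.phenotype,)))
        if r.mechanism not in om:
            violations.append(Violation(
                "dangling-id", f"marker target {r.mechanism} not in mechanism ontology",
                (r.mechanism,)))
        elif om.term(r.mechanism).category not in _MARKER_TARGET_CATEGORIES:
            violations.append(Violation(
                "marker-target-category",
                f"marker target {r.mechanism} has category "
                f"{om.term(r.mechanism).category!r}; expected one of {_MARKER_TARGET_CATEGORIES}",
                (r.mechanism,)))
    for r in m.participants:
        if r.mechanism not in om:
            violations.append(Violation(
                "dangling-id", f"participant-rule interaction {r.mechanism} not in "
                "mechanism ontology", (r.mechanism,)))
        elif om.term(r.mechanism).category != _PARTICIPANT_SOURCE_CATEGORY:
            violations.append(Violation(
                "participant-source-category",
                f"participant rule sources {r.mechanism} of category "
                f"{om.term(r.mechanism).category!r}; expected {_PARTICIPANT_SOURCE_CATEGORY!r}",
                (r.mechanism,)))
        if len(r.participants) < 2:
            violations.append(Violation(
                "participant-arity",
                f"participant rule for {r.mechanism} needs >= 2 participants, "
                f"got {len(r.participants)}", (r.mechanism,)))
        for molecule in sorted(r.participants):
            if molecule not in op:
                violations.append(Violation(
                    "dangling-id", f"participant {molecule} not in phenotype ontology",
                    (molecule,)))
    return violations


def derive_transition(a: AnnotationProfile, b: AnnotationProfile, m: MechanismMap,
                      op: Ontology, om: Ontology,
                      vocab: QualityVocabulary = DEFAULT_VOCABULARY) -> TransitionProfile:
    """Differential analysis of phenotype profiles a (earlier) and b (later).

    Marker rule s -> t: s flips absent->present  =>  (t, up);
    present->absent  =>  (t, down).  Participant rule i <- M: all of M
    present in b with at least one asserted absent in a  =>  (i, up);
    the mirror gives (i, down).  Presence/absence means the literal
    ``present``/``absent`` modifier; extension qualities do not count.
    """
    for p in (a, b):
        if p.kind != PHENOTYPE_KIND:
            raise ValueError(f"derive_transition needs phenotype profiles; {p.id} is {p.kind}")
    if a.timestamp is not None:
        if b.timestamp is None:
            raise ValueError("later profile lacks a timestamp while the earlier one has one")
        if not a.timestamp < b.timestamp:
            raise ValueError(
                f"timestamps must increase: {a.id}@{a.timestamp} -> {b.id}@{b.timestamp}")

    def present(p: AnnotationProfile, t: str) -> bool:
        return p.asserts(t, "present")

    def absent(p: AnnotationProfile, t: str) -> bool:
        return p.asserts(t, "absent")

    up = vocab.quality("up")
    down = vocab.quality("down")
    derived: set[EQAnnotation] = set()
    for r in m.markers:
        if absent(a, r.phenotype) and present(b, r.phenotype):
            derived.add(EQAnnotation(r.mechanism, up))
        elif present(a, r.phenotype) and absent(b, r.phenotype):
            derived.add(EQAnnotation(r.mechanism, down))
    for r in m.participants:
        mols = sorted(r.participants)
        if all(present(b, x) for x in mols) and any(absent(a, x) for x in mols):
            derived.add(EQAnnotation(r.mechanism, up))
        elif all(present(a, x) for x in mols) and any(absent(b, x) for x in mols):
            derived.add(EQAnnotation(r.mechanism, down))

    prof = AnnotationProfile(
        id=f"{a.id}->{b.id}", kind=MECHANISM_CHANGE_KIND,
        annotations=frozenset(derived), timestamp=b.timestamp)
    return TransitionProfile(profile=prof, start_h=a.timestamp, end_h=b.timestamp)


def series_transitions(s: ProfileSeries, m: MechanismMap, op: Ontology, om: Ontology,
                       vocab: QualityVocabulary = DEFAULT_VOCABULARY
                       ) -> tuple[TransitionProfile, ...]:
    """Consecutive-pair transitions: n profiles yield n-1 transitions."""
    if len(s) < 2:
        raise ValueError("a series of at least two profiles is needed")
    return tuple(
        derive_transition(a, b, m, op, om, vocab)
        for a, b in zip(s.profiles, s.profiles[1:])
    )


# -- MechanismMap TSV ---------------------------------------------------
#
# rule_type<TAB>mechanism_id<TAB>phenotype_ids   (comma-separated)

MAP_HEADER = ("rule_type", "mechanism_id", "phenotype_ids")


def read_mechanism_map_tsv(path: str | Path) -> MechanismMap:
    markers: list[MarkerRule] = []
    participants: list[ParticipantRule] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or tuple(header) != MAP_HEADER:
            raise ValueError(f"bad mechanism-map header {header!r}, expected {list(MAP_HEADER)}")
        for row_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 3:
                raise ValueError(f"row {row_no}: expected 3 columns, got {len(row)}")
            rule_type, mech, phen = row
            ids = [x for x in phen.split(",") if x]
            if rule_type == "marker":
                if len(ids) != 1:
                    raise ValueError(f"row {row_no}: marker rule needs exactly one phenotype id")
                markers.append(MarkerRule(phenotype=ids[0], mechanism=mech))
            elif rule_type == "participant":
                participants.append(ParticipantRule(mechanism=mech, participants=frozenset(ids)))
            else:
                raise ValueError(f"row {row_no}: unknown rule_type {rule_type!r}")
    return MechanismMap(markers=tuple(markers), participants=tuple(participants))


def write_mechanism_map_tsv(m: MechanismMap, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(MAP_HEADER)
        for r in sorted(m.markers, key=lambda r: (r.mechanism, r.phenotype)):
            writer.writerow(["marker", r.mechanism, r.phenotype])
        for r in sorted(m.participants, key=lambda r: r.mechanism):
            writer.writerow(["participant", r.mechanism, ",".join(sorted(r.participants))])
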