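"""EQ annotation profiles: entity terms paired with quality modifiers.

A cell state (phenotype profile) is a time-stamped set of pairs such as
``(Occludin, present)`` or ``(Cell membrane, joined)``; a cell-transition
description (mechanism-change profile) pairs mechanism terms with change
modifiers, e.g. ``(Interaction Occludin-JAM, up)``.  The core modifier
vocabulary is exactly {present, absent, up, moderately_up, down}; further
state modifiers (like ``joined``) are configured extensions that must
declare a polarity.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .onto import Ontology, Violation

PHENOTYPE_KIND = "phenotype"
MECHANISM_CHANGE_KIND = "mechanism-change"
PROFILE_KINDS = (PHENOTYPE_KIND, MECHANISM_CHANGE_KIND)

POSITIVE = "positive"
NEGATIVE = "negative"

#: core modifiers and their polarities
CORE_QUALITIES: dict[str, str] = {
    "present": POSITIVE,
    "absent": NEGATIVE,
    "up": POSITIVE,
    "moderately_up": POSITIVE,
    "down": NEGATIVE,
}
STATE_QUALITIES = ("present", "absent")
CHANGE_QUALITIES = ("up", "moderately_up", "down")


@dataclass(frozen=True)
class Quality:
    """A modifier with a fixed polarity (e.g. present/+, down/-)."""

    name: str
    polarity: str

    def __post_init__(self) -> None:
        if self.polarity not in (POSITIVE, NEGATIVE):
            raise ValueError(f"quality polarity must be positive/negative, got {self.polarity!r}")


class QualityVocabulary:
    """Core modifiers plus configured extension modifiers.

    Extensions (default: ``joined``, positive) are state qualities, usable
    in phenotype profiles only; change qualities are reserved for
    mechanism-change profiles.
    """

    def __init__(self, extensions: Mapping[str, str] | None = None):
        if extensions is None:
            extensions = {"joined": POSITIVE}
        self._qualities: dict[str, Quality] = {
            name: Quality(name, pol) for name, pol in CORE_QUALITIES.items()
        }
        self.extensions: tuple[str, ...] = tuple(sorted(extensions))
        for name, pol in extensions.items():
            if name in CORE_QUALITIES:
                raise ValueError(f"extension {name!r} collides with a core modifier")
            self._qualities[name] = Quality(name, pol)

    def __contains__(self, name: str) -> bool:
        return name in self._qualities

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self._qualities))

    def quality(self, name: str) -> Quality:
        try:
            return self._qualities[name]
        except KeyError:
            raise KeyError(f"unknown quality modifier {name!r}") from None

    def is_state(self, name: str) -> bool:
        return name in STATE_QUALITIES or name in self.extensions

    def is_change(self, name: str) -> bool:
        return name in CHANGE_QUALITIES

    def allowed_for(self, kind: str) -> tuple[str, ...]:
        if kind == PHENOTYPE_KIND:
            return tuple(q for q in self if self.is_state(q))
        return CHANGE_QUALITIES


DEFAULT_VOCABULARY = QualityVocabulary()


@dataclass(frozen=True)
class EQAnnotation:
    """One entity-quality pair."""

    entity: str
    quality: Quality


@dataclass(frozen=True)
class AnnotationProfile:
    """A time-stamped set of EQ annotations describing one cell state or
    one mechanism change.

    ``timestamp`` is hours after intervention; ``None`` means
    before/without intervention.
    """

    id: str
    kind: str
    annotations: frozenset[EQAnnotation]
    timestamp: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in PROFILE_KINDS:
            raise ValueError(f"profile kind must be one of {PROFILE_KINDS}, got {self.kind!r}")
        object.__setattr__(self, "annotations", frozenset(self.annotations))

    def entities(self) -> frozenset[str]:
        return frozenset(a.entity for a in self.annotations)

    def qualities_of(self, entity: str) -> set[Quality]:
        return {a.quality for a in self.annotations if a.entity == entity}

    def asserts(self, entity: str, quality_name: str) -> bool:
        return any(a.entity == entity and a.quality.name == quality_name for a in self.annotations)

    def replace(self, **kw) -> "AnnotationProfile":
        data = {"id": self.id, "kind": self.kind, "annotations": self.annotations,
                "timestamp": self.timestamp}
        data.update(kw)
        return AnnotationProfile(**data)

    def __len__(self) -> int:
        return len(self.annotations)


def profile(pid: str, kind: str, pairs: Iterable[tuple[str, str]],
            timestamp: float | None = None,
            vocab: QualityVocabulary = DEFAULT_VOCABULARY) -> AnnotationProfile:
    """Convenience constructor from (entity id, quality name) pairs."""
    anns = frozenset(EQAnnotation(e, vocab.quality(q)) for e, q in pairs)
    return AnnotationProfile(id=pid, kind=kind, annotations=anns, timestamp=timestamp)


@dataclass(frozen=True)
class ProfileSeries:
    """Phenotype profiles of one cell through time.

    Timestamps are strictly increasing; the first may be unset, standing
    for the state before the intervention.
    """

    profiles: tuple[AnnotationProfile, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "profiles", tuple(self.profiles))
        for p in self.profiles:
            if p.kind != PHENOTYPE_KIND:
                raise ValueError(f"series admits phenotype profiles only, {p.id} is {p.kind}")
        stamps = [p.timestamp for p in self.profiles]
        for i, t in enumerate(stamps):
            if t is None and i > 0:
                raise ValueError("only the first profile of a series may have an unset timestamp")
        set_stamps = [t for t in stamps if t is not None]
        if any(b <= a for a, b in zip(set_stamps, set_stamps[1:])):
            raise ValueError(f"series timestamps must be strictly increasing, got {stamps}")

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self) -> Iterator[AnnotationProfile]:
        return iter(self.profiles)


@dataclass(frozen=True)
class Corpus:
    """Profiles of one kind over one ontology, unique ids."""

    profiles: tuple[AnnotationProfile, ...]

    def __post_init__(self) -> None:
        # canonical order: by profile id (makes equality representation-free)
        object.__setattr__(self, "profiles", tuple(sorted(self.profiles, key=lambda p: p.id)))
        ids = [p.id for p in self.profiles]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate profile ids in corpus: {dupes}")
        kinds = {p.kind for p in self.profiles}
        if len(kinds) > 1:
            raise ValueError(f"corpus mixes profile kinds: {sorted(kinds)}")

    @property
    def kind(self) -> str | None:
        return self.profiles[0].kind if self.profiles else None

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self) -> Iterator[AnnotationProfile]:
        return iter(self.profiles)

    def __getitem__(self, pid: str) -> AnnotationProfile:
        for p in self.profiles:
            if p.id == pid:
                return p
        raise KeyError(pid)


# -- validation ---------------------------------------------------------

def validate_profile(p: AnnotationProfile, o: Ontology,
                     vocab: QualityVocabulary = DEFAULT_VOCABULARY) -> list[Violation]:
    """Unknown entities, kind/quality mismatches and polarity conflicts."""
    violations: list[Violation] = []
    if (p.kind == PHENOTYPE_KIND) != (o.kind == "phenotype"):
        violations.append(Violation(
            "ontology-kind-mismatch",
            f"profile {p.id} of kind {p.kind} validated against a {o.kind} ontology",
            (p.id,)))
    for a in sorted(p.annotations, key=lambda a: (a.entity, a.quality.name)):
        if a.entity not in o:
            violations.append(Violation(
                "unknown-entity",
                f"profile {p.id}: entity {a.entity} not in ontology", (p.id, a.entity)))
        if a.quality.name not in vocab:
            violations.append(Violation(
                "unknown-quality",
                f"profile {p.id}: quality {a.quality.name!r} not in vocabulary",
                (p.id, a.entity)))
        elif a.quality.name not in vocab.allowed_for(p.kind):
            violations.append(Violation(
                "kind-quality-mismatch",
                f"profile {p.id}: quality {a.quality.name!r} not allowed in a {p.kind} profile",
                (p.id, a.entity)))
    by_entity: dict[str, set[str]] = {}
    for a in p.annotations:
        by_entity.setdefault(a.entity, set()).add(a.quality.polarity)
    for entity in sorted(e for e, pols in by_entity.items() if len(pols) > 1):
        violations.append(Violation(
            "polarity-conflict",
            f"profile {p.id}: entity {entity} carries both a positive and a negative quality",
            (p.id, entity)))
    if p.timestamp is not None and p.timestamp < 0:
        violations.append(Violation(
            "negative-timestamp", f"profile {p.id}: timestamp {p.timestamp} < 0", (p.id,)))
    return violations


def validate_corpus(c: Corpus, o: Ontology,
                    vocab: QualityVocabulary = DEFAULT_VOCABULARY) -> list[Violation]:
    out: list[Violation] = []
    for p in c:
        out.extend(validate_profile(p, o, vocab))
    return out


# -- TSV layout ---------------------------------------------------------
#
# profile_id<TAB>kind<TAB>timestamp_h<TAB>entity_id<TAB>quality
# one annotation per row; timestamp repeated on each row; "." = unset

TSV_HEADER = ("profile_id", "kind", "timestamp_h", "entity_id", "quality")


class ProfileTsvError(ValueError):
    def __init__(self, message: str, row: int | None = None):
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)
        self.row = row


def _format_timestamp(t: float | None) -> str:
    if t is None:
        return "."
    if float(t) == int(t):
        return str(int(t))
    return repr(float(t))


def _parse_timestamp(text: str, row: int) -> float | None:
    if text == ".":
        return None
    try:
        return float(text)
    except ValueError:
        raise ProfileTsvError(f"unparseable timestamp {text!r}", row) from None


def read_profiles_tsv(path: str | Path, o: Ontology,
                      vocab: QualityVocabulary = DEFAULT_VOCABULARY) -> Corpus:
    """Read a profile TSV, group rows into profiles, and validate them.

    Any malformed row or invalid profile fails the read with row numbers.
    """
    groups: dict[str, dict] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ProfileTsvError("empty file (missing header)") from None
        if tuple(header) != TSV_HEADER:
            raise ProfileTsvError(f"bad header {header!r}, expected {list(TSV_HEADER)}", 1)
        for row_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 5:
                raise ProfileTsvError(f"expected 5 columns, got {len(row)}", row_no)
            pid, kind, ts_text, entity, quality = row
            if kind not in PROFILE_KINDS:
                raise ProfileTsvError(f"unknown profile kind {kind!r}", row_no)
            ts = _parse_timestamp(ts_text, row_no)
            if quality not in vocab:
                raise ProfileTsvError(f"unknown quality {quality!r}", row_no)
            g = groups.setdefault(pid, {"kind": kind, "timestamp": ts, "pairs": set(),
                                        "first_row": row_no})
            if g["kind"] != kind:
                raise ProfileTsvError(
                    f"profile {pid!r} mixes kinds {g['kind']!r} and {kind!r}", row_no)
            if g["timestamp"] != ts:
                raise ProfileTsvError(
                    f"profile {pid!r} has inconsistent timestamps "
                    f"({g['timestamp']} vs {ts})", row_no)
            g["pairs"].add((entity, quality))

    profiles = []
    for pid in groups:
        g = groups[pid]
        profiles.append(profile(pid, g["kind"], g["pairs"], g["timestamp"], vocab))
    corpus = Corpus(tuple(sorted(profiles, key=lambda p: p.id)))
    violations = validate_corpus(corpus, o, vocab)
    if violations:
        raise ProfileTsvError(
            "profiles fail validation: " + "; ".join(str(v) for v in violations))
    return corpus


def write_profiles_tsv(c: Corpus, path: str | Path) -> None:
    """Write a corpus deterministically: rows sorted by profile id, then
    entity id, then quality name. Round-trips with :func:`read_profiles_tsv`."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_HEADER)
        for p in sorted(c, key=lambda p: p.id):
            ts = _format_timestamp(p.timestamp)
            for a in sorted(p.annotations, key=lambda a: (a.entity, a.quality.name)):
                writer.writerow([p.id, p.kind, ts, a.entity, a.quality.name])
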