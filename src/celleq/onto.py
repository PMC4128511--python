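"""Ontologies of cell parts (continuants) and cell mechanisms (occurrents).

An :class:`Ontology` is a set of typed terms connected by two directed,
individually acyclic relations:

``is_a``
    ordinary subsumption, read subclass -> superclass;
``has_part``
    all-some parthood, read whole -> necessary part: *every* instance of
    the subject has *some* instance of the object as part.

``has_part`` (rather than ``part_of``) is the parthood primitive because a
molecule such as Occludin may sit in many structures, while a tight
junction *must* contain Occludin; the whole determines its parts.  This
choice fixes the direction of annotation propagation: a positive
annotation of a whole covers all of its necessary parts and all of its
superclasses (:func:`Ontology.positive_scope`), and a hard absence covers
everything that requires the absent term (:func:`Ontology.negative_scope`).
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

PHENOTYPE = "phenotype"
MECHANISM = "mechanism"

#: namespace/category vocabulary per ontology kind
PHENOTYPE_CATEGORIES = ("cell", "structure", "ultrastructure", "molecule")
MECHANISM_CATEGORIES = (
    "mechanism-network",
    "ultrastructural-event",
    "molecular-interaction",
)
CATEGORIES = {PHENOTYPE: PHENOTYPE_CATEGORIES, MECHANISM: MECHANISM_CATEGORIES}

IS_A = "is_a"
HAS_PART = "has_part"
RELATIONS = (IS_A, HAS_PART)

#: ontology-name header values used by the OBO subset dialect
_KIND_TO_OBO = {PHENOTYPE: "cell-phenotype", MECHANISM: "cell-mechanism"}
_OBO_TO_KIND = {v: k for k, v in _KIND_TO_OBO.items()}


class UnknownTermError(KeyError):
    """A term id was looked up that the ontology does not contain."""

    def __init__(self, term_id: str):
        super().__init__(term_id)
        self.term_id = term_id

    def __str__(self) -> str:  # KeyError repr-quotes its arg; keep it readable
        return f"unknown term id: {self.term_id!r}"


class OboParseError(ValueError):
    """Malformed input in the OBO subset dialect."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class Term:
    """A named class in one of the two ontologies."""

    id: str
    label: str
    category: str


@dataclass(frozen=True)
class Edge:
    """A directed ``is_a`` or ``has_part`` assertion between two terms."""

    subject: str
    relation: str
    object: str


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by a validator."""

    code: str
    message: str
    subjects: tuple[str, ...] = ()

    def __str__(self) -> str:
        return f"[{self.code}] {self.message}"


class Ontology:
    """Terms plus is_a/has_part edges, with memoized scope queries.

    The constructor accepts arbitrary (possibly invalid) content so that
    :func:`validate_ontology` can report every problem; scope queries are
    well-defined on any input because they are plain reachability.
    """

    def __init__(self, kind: str, terms: Iterable[Term], edges: Iterable[Edge]):
        if kind not in (PHENOTYPE, MECHANISM):
            raise ValueError(f"unknown ontology kind: {kind!r}")
        self.kind = kind
        self._term_list: list[Term] = list(terms)
        self.terms: dict[str, Term] = {}
        for t in self._term_list:
            self.terms.setdefault(t.id, t)
        self.edges: tuple[Edge, ...] = tuple(edges)
        # forward = direction a positive annotation flows:
        #   is_a subclass->superclass, has_part whole->part
        self._forward: dict[str, set[str]] = {}
        self._reverse: dict[str, set[str]] = {}
        for e in self.edges:
            self._forward.setdefault(e.subject, set()).add(e.object)
            self._reverse.setdefault(e.object, set()).add(e.subject)
        self._scope_cache: dict[tuple[str, bool], frozenset[str]] = {}

    # -- basic protocol -------------------------------------------------
    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __iter__(self) -> Iterator[str]:
        return iter(self.terms)

    def __len__(self) -> int:
        return len(self.terms)

    def term(self, term_id: str) -> Term:
        try:
            return self.terms[term_id]
        except KeyError:
            raise UnknownTermError(term_id) from None

    def has_part_edges(self) -> list[Edge]:
        return [e for e in self.edges if e.relation == HAS_PART]

    # -- scopes ---------------------------------------------------------
    def _reach(self, start: str, adj: dict[str, set[str]]) -> frozenset[str]:
        seen = {start}
        queue = deque([start])
        while queue:
            for nxt in adj.get(queue.popleft(), ()):
                if nxt not in seen:
                    seen.add(nxt)
                    queue.append(nxt)
        return frozenset(seen)

    def positive_scope(self, term_id: str) -> frozenset[str]:
        """All terms a positive annotation of ``term_id`` logically covers.

        Reflexive-transitive closure following is_a subclass->superclass
        and has_part whole->part: annotating a whole as present (or a
        process start as up) entails the same for every superclass and
        every necessary part.
        """
        if term_id not in self.terms:
            raise UnknownTermError(term_id)
        key = (term_id, True)
        if key not in self._scope_cache:
            self._scope_cache[key] = self._reach(term_id, self._forward)
        return self._scope_cache[key]

    def negative_scope(self, term_id: str) -> frozenset[str]:
        """All terms an 'absent' annotation of ``term_id`` logically covers.

        The contrapositive of the all-some reading: if a necessary part is
        absent, so is every whole that requires it, and if a superclass is
        absent, so is every subclass.  Equals {s : term_id in
        positive_scope(s)}.
        """
        if term_id not in self.terms:
            raise UnknownTermError(term_id)
        key = (term_id, False)
        if key not in self._scope_cache:
            self._scope_cache[key] = self._reach(term_id, self._reverse)
        return self._scope_cache[key]

    def __repr__(self) -> str:
        return f"Ontology(kind={self.kind!r}, terms={len(self.terms)}, edges={len(self.edges)})"


def positive_scope(o: Ontology, term_id: str) -> frozenset[str]:
    return o.positive_scope(term_id)


def negative_scope(o: Ontology, term_id: str) -> frozenset[str]:
    return o.negative_scope(term_id)


# -- validation ---------------------------------------------------------

def _cycle_members(nodes: Iterable[str], edges: list[Edge]) -> set[str]:
    """Nodes that sit on a directed cycle of the given edge set (Kahn)."""
    out: dict[str, set[str]] = {n: set() for n in nodes}
    indeg: dict[str, int] = {n: 0 for n in nodes}
    for e in edges:
        if e.subject in out and e.object in indeg and e.object not in out[e.subject]:
            out[e.subject].add(e.object)
            indeg[e.object] += 1
    queue = deque(n for n, d in indeg.items() if d == 0)
    removed = 0
    while queue:
        n = queue.popleft()
        removed += 1
        for m in out[n]:
            indeg[m] -= 1
            if indeg[m] == 0:
                queue.append(m)
    return {n for n, d in indeg.items() if d > 0}


def validate_ontology(o: Ontology) -> list[Violation]:
    """Every invariant violation in ``o``; empty list iff valid."""
    violations: list[Violation] = []

    seen: set[str] = set()
    for t in o._term_list:
        if t.id in seen:
            violations.append(
                Violation("duplicate-id", f"term id {t.id} declared more than once", (t.id,))
            )
        seen.add(t.id)
        if not t.label:
            violations.append(Violation("empty-label", f"term {t.id} has an empty label", (t.id,)))
        if t.category not in CATEGORIES[o.kind]:
            violations.append(
                Violation(
                    "category-kind-mismatch",
                    f"term {t.id} has category {t.category!r}, not valid in a "
                    f"{o.kind} ontology (expected one of {CATEGORIES[o.kind]})",
                    (t.id,),
                )
            )

    for e in o.edges:
        if e.relation not in RELATIONS:
            violations.append(
                Violation(
                    "unknown-relation",
                    f"edge {e.subject} -[{e.relation}]-> {e.object}: unknown relation",
                    (e.subject, e.object),
                )
            )
        if e.subject == e.object:
            violations.append(
                Violation("self-edge", f"edge {e.subject} -[{e.relation}]-> itself", (e.subject,))
            )
        for endpoint in (e.subject, e.object):
            if endpoint not in o.terms:
                violations.append(
                    Violation(
                        "dangling-endpoint",
                        f"edge {e.subject} -[{e.relation}]-> {e.object}: "
                        f"{endpoint} is not a term of this ontology",
                        (endpoint,),
                    )
                )

    for relation in RELATIONS:
        members = _cycle_members(o.terms, [e for e in o.edges if e.relation == relation])
        if members:
            violations.append(
                Violation(
                    "cycle",
                    f"{relation} graph contains a cycle through {{{', '.join(sorted(members))}}}",
                    tuple(sorted(members)),
                )
            )
    return violations


# -- OBO subset dialect -------------------------------------------------
#
# format-version: 1.4
# ontology: cell-phenotype | cell-mechanism
#
# [Term]
# id: CPH:0000001
# name: Epithelial cell
# namespace: cell
# is_a: CPH:0000002
# relationship: has_part CPH:0000003

_KNOWN_TERM_TAGS = {"id", "name", "namespace", "is_a", "relationship"}


def _strip_obo_comment(value: str) -> str:
    return value.split("!", 1)[0].strip()


def read_obo_subset(path: str | Path, kind: str | None = None) -> Ontology:
    """Parse an OBO-subset file into a validated :class:`Ontology`.

    ``kind`` overrides/defaults the ontology kind; otherwise it is taken
    from the ``ontology:`` header or inferred from term namespaces.
    Unknown tags inside ``[Term]`` stanzas are ignored with a warning;
    anything structurally wrong raises :class:`OboParseError` with the
    offending line number.
    """
    text = Path(path).read_text(encoding="utf-8")
    terms: list[Term] = []
    edges: list[Edge] = []
    header_kind: str | None = None

    in_term = False
    in_other_stanza = False
    current: dict[str, str] = {}
    current_rel: list[tuple[str, str]] = []  # (relation target, raw) within stanza
    stanza_line = 0

    def flush(line_no: int) -> None:
        nonlocal current, current_rel
        if not in_term:
            return
        if "id" not in current:
            raise OboParseError("[Term] stanza without an id tag", stanza_line)
        tid = current["id"]
        terms.append(Term(id=tid, label=current.get("name", ""), category=current.get("namespace", "")))
        for parent in current.get("_is_a", "").split("\x00"):
            if parent:
                edges.append(Edge(subject=tid, relation=IS_A, object=parent))
        for target, _ in current_rel:
            edges.append(Edge(subject=tid, relation=HAS_PART, object=target))
        current = {}
        current_rel = []

    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("!"):
            continue
        if line.startswith("["):
            flush(line_no)
            if line == "[Term]":
                in_term, in_other_stanza = True, False
                stanza_line = line_no
            else:
                # other stanza kinds (e.g. [Typedef]) are outside the dialect
                raise OboParseError(f"unsupported stanza {line}", line_no)
            continue
        if ":" not in line:
            raise OboParseError(f"expected 'tag: value', got {line!r}", line_no)
        tag, value = line.split(":", 1)
        tag = tag.strip()
        value = _strip_obo_comment(value)
        if not in_term and not in_other_stanza:
            # header clause
            if tag == "ontology":
                header_kind = _OBO_TO_KIND.get(value, None)
                if header_kind is None and value in (PHENOTYPE, MECHANISM):
                    header_kind = value
                elif header_kind is None:
                    logger.warning("line %d: unrecognized ontology header %r", line_no, value)
            elif tag != "format-version":
                logger.warning("line %d: ignoring header tag %r", line_no, tag)
            continue
        # term stanza clause
        if tag == "relationship":
            parts = value.split()
            if len(parts) != 2:
                raise OboParseError(
                    f"relationship must be 'has_part <id>', got {value!r}", line_no
                )
            rel, target = parts
            if rel != HAS_PART:
                raise OboParseError(
                    f"unknown relationship type {rel!r} (this dialect admits only has_part)",
                    line_no,
                )
            current_rel.append((target, value))
        elif tag == "is_a":
            if not value:
                raise OboParseError("is_a with empty target", line_no)
            current["_is_a"] = current.get("_is_a", "") + value + "\x00"
        elif tag in _KNOWN_TERM_TAGS:
            if tag == "id" and not value:
                raise OboParseError("empty id tag", line_no)
            current[tag] = value
        else:
            logger.warning("line %d: ignoring unknown tag %r in [Term] stanza", line_no, tag)
    flush(len(text.splitlines()) + 1)

    resolved_kind = kind or header_kind
    if resolved_kind is None:
        cats = {t.category for t in terms}
        resolved_kind = MECHANISM if cats & set(MECHANISM_CATEGORIES) else PHENOTYPE
    onto = Ontology(resolved_kind, terms, edges)
    violations = validate_ontology(onto)
    if violations:
        raise OboParseError(
            "ontology fails validation: " + "; ".join(str(v) for v in violations)
        )
    return onto


def write_obo_subset(o: Ontology, path: str | Path) -> None:
    """Serialize ``o`` deterministically (terms by id, fixed tag order).

    Refuses invalid ontologies; ``read_obo_subset`` on the output
    reproduces ``o`` exactly, and serialization is byte-stable.
    """
    violations = validate_ontology(o)
    if violations:
        raise ValueError(
            "refusing to write invalid ontology: " + "; ".join(str(v) for v in violations)
        )
    is_a: dict[str, list[str]] = {}
    parts: dict[str, list[str]] = {}
    for e in o.edges:
        (is_a if e.relation == IS_A else parts).setdefault(e.subject, []).append(e.object)

    lines = ["format-version: 1.4", f"ontology: {_KIND_TO_OBO[o.kind]}", ""]
    for tid in sorted(o.terms):
        t = o.terms[tid]
        lines.append("[Term]")
        lines.append(f"id: {t.id}")
        lines.append(f"name: {t.label}")
        lines.append(f"namespace: {t.category}")
        for parent in sorted(set(is_a.get(tid, ()))):
            lines.append(f"is_a: {parent}")
        for part in sorted(set(parts.get(tid, ()))):
            lines.append(f"relationship: has_part {part}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8", newline="\n")
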