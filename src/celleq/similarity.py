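"""Information content and profile similarity over the propagation order.

Information content is corpus-frequency based: IC(t) = -log2(count(t)/N)
in bits, where count(t) is the number of profiles carrying a
positive-polarity annotation of t *after propagation*.  Because positive
annotations flow whole -> part, a necessary part accumulates at least the
annotations of every whole that requires it, so a whole process always
has information content at least as high as each of its necessary parts.

Term similarity is Resnik-style, with the "most informative common
ancestor" re-read along the same order: the most informative common
*propagation target* (shared necessary part or superclass) of the two
terms.  Profile similarity combines term similarities by symmetric
best-match averaging (BMA), weighted by a quality-compatibility table;
simGIC (IC-weighted Jaccard over annotation sets) is the secondary
measure.  Search ranks a corpus against a query profile by BMA — a
BLAST-like search in annotation space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .onto import Ontology
from .profiles import (
    POSITIVE,
    AnnotationProfile,
    Corpus,
    DEFAULT_VOCABULARY,
    Quality,
    QualityVocabulary,
)
from .propagation import SOUND, propagate_corpus, propagate_profile


@dataclass(frozen=True)
class ICTable:
    """Per-term information content (bits) over a propagated corpus."""

    ic: Mapping[str, float]
    counts: Mapping[str, int]
    n: int
    mode: str

    @property
    def ic_max(self) -> float:
        return math.log2(self.n)

    def __getitem__(self, term_id: str) -> float:
        return self.ic.get(term_id, self.ic_max)


def information_content(c: Corpus, o: Ontology, mode: str = SOUND) -> ICTable:
    """IC(t) = -log2(count(t)/N); unannotated terms get IC_max = log2 N."""
    if len(c) == 0:
        raise ValueError("information content is undefined on an empty corpus")
    propagated = propagate_corpus(c, o, mode)
    counts = dict.fromkeys(o.terms, 0)
    for p in propagated:
        positives = {a.entity for a in p.annotations if a.quality.polarity == POSITIVE}
        for t in positives:
            if t in counts:
                counts[t] += 1
    n = len(c)
    ic = {
        t: (-math.log2(k / n) if k > 0 else math.log2(n))
        for t, k in counts.items()
    }
    return ICTable(ic=ic, counts=counts, n=n, mode=mode)


def term_similarity(t1: str, t2: str, ic: ICTable, o: Ontology) -> float:
    """Max IC over the common positive-propagation targets of t1 and t2.

    The shared targets are the necessary parts / superclasses both terms
    cover; 0 if they share none. Symmetric by construction.
    """
    common = o.positive_scope(t1) & o.positive_scope(t2)
    if not common:
        return 0.0
    return max(ic[t] for t in common)


@dataclass(frozen=True)
class CompatibilityTable:
    """Symmetric quality-match weights kappa(q1, q2) in [0, 1].

    kappa(q, q) = 1 always; cross-polarity pairs are forced to 0.  The
    default off-diagonal table is kappa(up, moderately_up) = 0.5 and 0
    elsewhere; overridable via :func:`default_compatibility` weights.
    """

    weights: Mapping[frozenset[str], float] = field(default_factory=dict)

    def kappa(self, q1: Quality, q2: Quality) -> float:
        if q1.polarity != q2.polarity:
            return 0.0
        if q1.name == q2.name:
            return 1.0
        return self.weights.get(frozenset((q1.name, q2.name)), 0.0)


def default_compatibility(vocab: QualityVocabulary = DEFAULT_VOCABULARY,
                          overrides: Mapping[tuple[str, str], float] | None = None
                          ) -> CompatibilityTable:
    weights: dict[frozenset[str], float] = {frozenset(("up", "moderately_up")): 0.5}
    if overrides:
        for (a, b), w in overrides.items():
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"kappa({a},{b}) = {w} outside [0,1]")
            if vocab.quality(a).polarity != vocab.quality(b).polarity and w != 0.0:
                raise ValueError(f"cross-polarity pair ({a},{b}) must have weight 0")
            weights[frozenset((a, b))] = w
    return CompatibilityTable(weights=weights)


DEFAULT_COMPATIBILITY = default_compatibility()


def quality_compatibility(q1: Quality, q2: Quality,
                          tbl: CompatibilityTable = DEFAULT_COMPATIBILITY) -> float:
    return tbl.kappa(q1, q2)


def profile_similarity_bma(p1: AnnotationProfile, p2: AnnotationProfile,
                           ic: ICTable, tbl: CompatibilityTable, o: Ontology) -> float:
    """Symmetric best-match average of kappa-weighted term similarities.

    Profiles are scored as given (propagate first if desired); an empty
    profile scores 0.
    """
    if p1.kind != p2.kind:
        raise ValueError(f"cannot compare a {p1.kind} profile with a {p2.kind} profile")
    a1 = sorted(p1.annotations, key=lambda a: (a.entity, a.quality.name))
    a2 = sorted(p2.annotations, key=lambda a: (a.entity, a.quality.name))
    if not a1 or not a2:
        return 0.0

    def best(a, others):
        return max(tbl.kappa(a.quality, b.quality) * term_similarity(a.entity, b.entity, ic, o)
                   for b in others)

    forward = sum(best(a, a2) for a in a1) / len(a1)
    backward = sum(best(b, a1) for b in a2) / len(a2)
    return (forward + backward) / 2.0


def profile_similarity_simgic(p1: AnnotationProfile, p2: AnnotationProfile,
                              ic: ICTable, o: Ontology) -> float:
    """IC-weighted Jaccard over (entity, polarity) sets, in [0, 1].

    Scored on the profiles as given; callers typically propagate first.
    If every term in the union has zero IC the measure degenerates to the
    plain Jaccard index of the sets.
    """
    if p1.kind != p2.kind:
        raise ValueError(f"cannot compare a {p1.kind} profile with a {p2.kind} profile")
    s1 = {(a.entity, a.quality.polarity) for a in p1.annotations}
    s2 = {(a.entity, a.quality.polarity) for a in p2.annotations}
    union = s1 | s2
    if not union:
        return 0.0
    inter = s1 & s2
    denom = sum(ic[t] for t, _ in union)
    if denom == 0.0:
        return len(inter) / len(union)
    return sum(ic[t] for t, _ in inter) / denom


@dataclass(frozen=True)
class SearchResult:
    """Ranked (profile id, score) hits, descending score, ties by id."""

    hits: tuple[tuple[str, float], ...]

    def __iter__(self):
        return iter(self.hits)

    def __len__(self) -> int:
        return len(self.hits)

    def ids(self) -> tuple[str, ...]:
        return tuple(pid for pid, _ in self.hits)


def similarity_search(query: AnnotationProfile, c: Corpus, ic: ICTable,
                      tbl: CompatibilityTable, o: Ontology, k: int,
                      mode: str = SOUND, measure: str = "bma") -> SearchResult:
    """Top-k corpus profiles most similar to ``query``.

    Query and corpus are propagated before scoring; ordering is total and
    deterministic (score descending, then profile id).  ``k`` larger than
    the corpus returns everything; ``k = 0`` returns nothing.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if len(c) and query.kind != c.kind:
        raise ValueError(f"query kind {query.kind} does not match corpus kind {c.kind}")
    pq = propagate_profile(query, o, mode)
    scored = []
    for p in propagate_corpus(c, o, mode):
        if measure == "bma":
            s = profile_similarity_bma(pq, p, ic, tbl, o)
        elif measure == "simgic":
            s = profile_similarity_simgic(pq, p, ic, o)
        else:
            raise ValueError(f"unknown measure {measure!r} (use 'bma' or 'simgic')")
        scored.append((p.id, s))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return SearchResult(hits=tuple(scored[:k]))
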