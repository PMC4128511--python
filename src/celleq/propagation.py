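"""Polarity-aware annotation propagation.

Asserted annotations imply further ones along the ontology:

* positive qualities (present, up, moderately_up, positive extensions)
  flow whole -> part and subclass -> superclass — a tight junction being
  present entails Occludin being present, because every tight junction
  has some Occludin as part;
* ``absent`` flows the contrapositive direction, part -> whole and
  superclass -> subclass — no Occludin, no tight junction;
* ``down`` does not propagate in the default *sound* mode: a whole
  process winding down does not entail each necessary part winding down,
  since parts may serve other wholes.  The *heuristic* mode propagates
  ``down`` whole -> part symmetrically to ``up`` for users who want it.

Propagation makes these implicit annotations explicit, which is what
lets frequency-based information content see that a whole process is
rarer (more informative) than its necessary parts.
"""

from __future__ import annotations

from .onto import Ontology, Violation
from .profiles import (
    NEGATIVE,
    POSITIVE,
    AnnotationProfile,
    Corpus,
    EQAnnotation,
)

SOUND = "sound"
HEURISTIC = "heuristic"
MODES = (SOUND, HEURISTIC)


def _check_mode(mode: str) -> None:
    if mode not in MODES:
        raise ValueError(f"propagation mode must be one of {MODES}, got {mode!r}")


def propagate_annotation(a: EQAnnotation, o: Ontology, mode: str = SOUND) -> frozenset[EQAnnotation]:
    """All annotations implied by ``a`` (always including ``a`` itself)."""
    _check_mode(mode)
    q = a.quality
    if q.polarity == POSITIVE:
        scope = o.positive_scope(a.entity)
    elif q.name == "down":
        scope = o.positive_scope(a.entity) if mode == HEURISTIC else frozenset({a.entity})
    else:
        # hard negatives (absent, negative extensions): contrapositive flow
        scope = o.negative_scope(a.entity)
    return frozenset(EQAnnotation(t, q) for t in scope)


def propagate_profile(p: AnnotationProfile, o: Ontology, mode: str = SOUND,
                      report: list[Violation] | None = None) -> AnnotationProfile:
    """Union of per-annotation propagation, conflicts resolved.

    If propagation produces both polarities on one entity, the directly
    asserted annotation wins and the conflict is appended to ``report``;
    if neither side is asserted, both inferred annotations are dropped
    (conservative) and the conflict is reported.  The result always
    contains every asserted annotation.
    """
    _check_mode(mode)
    pool: set[EQAnnotation] = set()
    for a in p.annotations:
        pool |= propagate_annotation(a, o, mode)

    asserted_polarity: dict[str, str] = {a.entity: a.quality.polarity for a in p.annotations}
    by_entity: dict[str, set[str]] = {}
    for a in pool:
        by_entity.setdefault(a.entity, set()).add(a.quality.polarity)

    keep: set[EQAnnotation] = set()
    for a in pool:
        pols = by_entity[a.entity]
        if len(pols) == 1:
            keep.add(a)
        elif a.entity in asserted_polarity:
            if a.quality.polarity == asserted_polarity[a.entity]:
                keep.add(a)
        # inferred-vs-inferred conflict: drop both sides
    if report is not None:
        for entity in sorted(e for e, pols in by_entity.items() if len(pols) > 1):
            winner = ("asserted annotation kept" if entity in asserted_polarity
                      else "both inferred annotations dropped")
            report.append(Violation(
                "propagation-conflict",
                f"profile {p.id}: propagation implies both polarities on {entity}; {winner}",
                (p.id, entity)))
    keep |= p.annotations  # asserted annotations always survive
    return p.replace(annotations=frozenset(keep))


def propagate_corpus(c: Corpus, o: Ontology, mode: str = SOUND,
                     report: list[Violation] | None = None) -> Corpus:
    """Element-wise :func:`propagate_profile`; ids and size preserved."""
    return Corpus(tuple(propagate_profile(p, o, mode, report) for p in c))
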