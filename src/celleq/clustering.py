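"""Clustering of phenotype profiles and of mechanism-change profiles.

Individual profiles are maximally fine-grained (any molecular difference
is a different phenotype); coarse cell types and transition classes are
recovered operationally by clustering profiles on semantic similarity.
Distances normalize BMA similarity Lin-style by the geometric mean of
the self-similarities, so they are corpus-scale independent and live in
[0, 1]; clustering is agglomerative with average linkage by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from .onto import Ontology
from .profiles import Corpus
from .similarity import (
    CompatibilityTable,
    ICTable,
    profile_similarity_bma,
)
from .propagation import SOUND, propagate_corpus

LINKAGES = ("average", "complete", "single")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric profile-profile distances in [0, 1], zero diagonal."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        object.__setattr__(self, "values", v)

    def distance(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])


@dataclass(frozen=True)
class Clustering:
    """Per-profile labels (contiguous from 1) plus the linkage record."""

    ids: tuple[str, ...]
    labels: tuple[int, ...]
    linkage: np.ndarray

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.ids, self.labels))


def distance_matrix(c: Corpus, ic: ICTable, tbl: CompatibilityTable, o: Ontology,
                    mode: str = SOUND, propagate: bool = True) -> DistanceMatrix:
    """d(p,q) = 1 - sim(p,q)/sqrt(sim(p,p) * sim(q,q)), clipped to [0,1].

    Similarity is BMA on (by default) propagated profiles; a profile with
    zero self-similarity is at distance 1 from everything but itself.
    """
    if len(c) < 2:
        raise ValueError("need at least two profiles to build a distance matrix")
    profiles = sorted(propagate_corpus(c, o, mode) if propagate else c,
                      key=lambda p: p.id)
    ids = tuple(p.id for p in profiles)
    n = len(profiles)
    self_sim = np.array([profile_similarity_bma(p, p, ic, tbl, o) for p in profiles])
    d = np.ones((n, n))
    np.fill_diagonal(d, 0.0)
    anns = [{(a.entity, a.quality.name) for a in p.annotations} for p in profiles]
    for i in range(n):
        for j in range(i + 1, n):
            if anns[i] == anns[j]:
                d[i, j] = d[j, i] = 0.0  # indistinguishable profiles
            elif self_sim[i] > 0 and self_sim[j] > 0:
                sim = profile_similarity_bma(profiles[i], profiles[j], ic, tbl, o)
                d[i, j] = d[j, i] = min(1.0, max(0.0, 1.0 - sim / np.sqrt(self_sim[i] * self_sim[j])))
    return DistanceMatrix(ids=ids, values=d)


def cluster_profiles(d: DistanceMatrix, k: int, linkage: str = "average") -> Clustering:
    """Agglomerative clustering of the distance matrix cut at k clusters.

    Deterministic for a given matrix: profiles enter in id order, so equal
    merge heights resolve by lexicographic pair order.  Labels are
    renumbered contiguously from 1 in order of first appearance.
    """
    n = len(d.ids)
    if not 1 <= k <= n:
        raise ValueError(f"k must be between 1 and {n}, got {k}")
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    z = hierarchy.linkage(squareform(d.values, checks=False), method=linkage)
    raw = hierarchy.fcluster(z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    labels = []
    for r in raw:
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        labels.append(relabel[r])
    return Clustering(ids=d.ids, labels=tuple(labels), linkage=z)


def adjusted_rand_index(labels_a: Sequence[int] | Mapping[str, int],
                        labels_b: Sequence[int] | Mapping[str, int]) -> float:
    """Standard ARI; 1 iff the partitions coincide, about 0 at chance."""
    if isinstance(labels_a, Mapping) and isinstance(labels_b, Mapping):
        if set(labels_a) != set(labels_b):
            raise ValueError("labelings cover different profile ids")
        keys = sorted(labels_a)
        a = [labels_a[k] for k in keys]
        b = [labels_b[k] for k in keys]
    else:
        a, b = list(labels_a), list(labels_b)  # type: ignore[arg-type]
        if len(a) != len(b):
            raise ValueError("labelings must have equal length")
    return float(adjusted_rand_score(a, b))
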