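# Methods

## Ontological model

Two ontologies are kept strictly apart. The *phenotype* ontology holds
continuants (categories: cell, structure, ultrastructure, molecule);
the *mechanism* ontology holds occurrents (mechanism-network,
ultrastructural-event, molecular-interaction). Profiles of kind
`phenotype` use state modifiers (present, absent, configured extensions
such as joined); profiles of kind `mechanism-change` use change
modifiers (up, moderately_up, down). The two spaces are never compared
directly; the only bridge is the explicit mechanism map used for
transition derivation.

Edges are `is_a` and `has_part`, each required to be acyclic on its
own (cycles are rejected at validation because the closures below
would be ill-defined on them). `has_part` carries all-some semantics:
every instance of the subject has some instance of the object as part.
`part_of` is deliberately *not* accepted — molecules and process parts
are not confined to one whole, so a universally quantified `part_of`
would be wrong for this domain — and an input file using it fails hard
rather than being silently inverted.

### Scopes and propagation

`positive_scope(t)` is the reflexive–transitive closure following
`is_a` subclass→superclass and `has_part` whole→part;
`negative_scope(t)` is the same closure over reversed edges, and the
two are dual by construction (`t ∈ negative_scope(s)` iff
`s ∈ positive_scope(t)`). Scopes are computed by breadth-first search
with per-ontology memoization; the contract (and the test suite) pins
them to a brute-force edge-relaxation fixpoint.

Propagation is polarity-aware:

| quality | sound mode | heuristic mode |
|---|---|---|
| positive (present, up, moderately_up, positive extensions) | positive scope | same |
| absent, negative extensions | negative scope | same |
| down | no propagation | positive scope |

`down` is inert in sound mode because a whole's decrease does not
entail a shared part's decrease; the heuristic mode is available for
users who want symmetric treatment. Conflicts created by propagation
(both polarities landing on one entity) are resolved in favour of the
directly asserted annotation — curated data outranks inference — and
surfaced in a report. When *both* sides are merely inferred there is no
principled winner, so both are dropped and the conflict reported;
propagation remains idempotent and a superset of its input either way.

## Information content and similarity

IC is corpus-frequency based, in bits, computed on the sound-propagated
corpus: `IC(t) = −log₂(count(t)/N)` where `count(t)` counts profiles
with a positive-polarity annotation of `t`. Terms never annotated get
`IC_max = log₂ N` — finite, without smoothing the observed counts.
Since positive annotations flow whole→part, `count(part) ≥
count(whole)` and therefore IC is anti-monotone along the positive
scope: a whole process is always at least as informative as each of
its necessary parts.

Term similarity is Resnik-style with the "common subsumer" re-read
along the propagation order: the most informative common
positive-propagation target. (A classic ancestor-based MICA would
invert the IC ordering here.) Profile measures:

* **BMA** — symmetric best-match average of
  `κ(q₁,q₂) · sim(e₁,e₂)`; the default κ table is 1 on the diagonal,
  0.5 for (up, moderately_up), 0 across polarities and 0 for all other
  pairs, overridable in the YAML config. Empty profiles score 0. Note
  a genuine property of BMA on nested profiles: after propagation, a
  strict superset profile can outscore an exact duplicate of the
  query, so "the identical corpus member ranks first" is guaranteed
  only among profiles not nested within one another's scopes.
* **simGIC** — IC-weighted Jaccard on (entity, polarity) sets, in
  [0, 1]; when every union term has IC 0 it degenerates to the plain
  Jaccard index. simGIC is the measure under which "reasoning improves
  similarity" is provable for profiles curated at different
  granularities of one programme: they intersect only after
  propagation, so the score can only rise (0 → positive on the MET
  example).

Search propagates the query and the corpus, scores by BMA (or simGIC),
and orders hits by descending score with ties broken by profile id, so
rankings are total and deterministic.

## Transition derivation

Transitions are derived from two phenotype profiles by qualitative
differential analysis through an explicit `MechanismMap`:

* marker rule `s → m`: `s` flipping absent→present yields `(m, up)`;
  present→absent yields `(m, down)`;
* participant rule `i ← M` (|M| ≥ 2 molecules): all of `M` present in
  the later profile with at least one asserted absent earlier yields
  `(i, up)`; the mirror yields `(i, down)`.

Annotation is open-world: entities unmentioned in a profile are
unknown, not absent, and fire nothing; presence/absence means the
literal `present`/`absent` modifier (a change to an extension quality
like `joined` is conservatively not a flip). Only the binary flip
derives changes; graded phenotype change to `moderately_up` mechanism
change is not derived. The derived profile inherits `start_h` from the
earlier and `end_h` from the later snapshot; a series of n profiles
yields n−1 chained transitions.

## Clustering

Distances are `d(p,q) = 1 − sim(p,q)/√(sim(p,p)·sim(q,q))` (Lin-style
normalization of BMA, corpus-scale independent), clipped to [0, 1],
computed on propagated profiles by default. Profiles with identical
annotation sets are at distance 0; a profile with zero self-similarity
(e.g. empty, or annotated only with IC-0 terms and nothing shared) is
at distance 1 from everything else. Clustering is agglomerative
(scipy), average linkage by default (robust for semantic-similarity
matrices), complete/single configurable; `k` is user-supplied since
the framework offers no model-selection criterion. Labels are
renumbered contiguously from 1 in order of first appearance, and the
whole procedure is deterministic for a given matrix.

## Fixtures and synthetic data

The two fixture ontologies encode the structure of the running
examples — the tight junction necessitating Occludin/JAM/Claudin, the
epithelial cell necessitating its junctions, the epithelial mechanism
network containing TJ-network → Occludin–JAM interaction, mitosis
containing S-phase — plus a small amount of invented glue (adherens
junction molecules E-cadherin/β-catenin and their interaction, a
Vimentin/cytoskeleton branch under the mesenchymal network, a
CDK1–CyclinB interaction under mitosis), flagged as such in the code.
The glue exists so that the example three-point time series can fire
at least one marker and one participant rule at each step, and so the
synthetic generator has three disjoint prototype regions.

The synthetic generator emulates a curated corpus with planted cluster
structure: per cluster a prototype mechanism-change programme (MET
start-up; mesenchymal/cytoskeletal programme; cell-cycle programme),
each profile obtained by (i) dropping each prototype annotation with
probability ε (default 0.1), (ii) re-annotating each survivor, with
probability g (default 0.3), onto a uniform member of its positive
scope — mixed-granularity curation as in real annotation practice —
and (iii) adding one spurious annotation on a uniform unused term with
probability ε. Defaults are 3 clusters × 10 profiles, seed 42. Because
shifted annotations can collide and merge (set semantics), the clean
expectation `E[|profile|] = |prototype|(1−ε) + ε` holds exactly only
with shifts disabled; the property test checks it at g = 0.

What the generator does **not** emulate: real expression noise,
correlated dropout, annotation errors with wrong polarity, ontologies
at realistic scale (thousands of terms), or inter-curator
disagreement. Passing the recovery test (ARI ≥ 0.9 with propagation;
within-cluster similarity strictly lower without) shows the pipeline
is coherent end-to-end under its own model of curation noise — not
that real curated corpora will cluster this cleanly.

## Numerical and formatting choices

* log base 2 throughout; IC and BMA reported in bits.
* Timestamps are numeric hours after intervention, "." when unset;
  integral values are written without a decimal point.
* OBO subset and profile TSV writers sort deterministically (terms by
  id; rows by profile id, entity, quality), so double serialization is
  byte-identical and write∘read is the identity on the dialect.
* Problem sizes in the tests and the acceptance script (random DAGs up
  to 50 terms, ~100 instances per check, corpora of ≤ 30 profiles) are
  chosen to exercise every code path exhaustively at small scale,
  where brute-force oracles are exact.

## Known limitations

* No OWL/DL reasoning: the closure rules above are the complete
  semantics; role chains, cardinalities and ABox reasoning are out of
  scope.
* The mechanism map is explicit curated input; it is not inferred from
  interaction databases.
* Cross-ontology ids (CL/GO/CELDA) pass through unchanged but carry no
  imported axioms.
* Search scores are not calibrated (no p-values); compare ranks, not
  absolute values, across corpora.
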