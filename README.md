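# celleq

Formal representation and analysis of **cell phenotypes** and
**cell-transition mechanisms** as entity–quality (EQ) annotation
profiles over two interlinked ontologies — an ontology of cell parts
(continuants: cells, structures, ultrastructures, molecules) and an
ontology of cell mechanisms (occurrents: networks of mechanisms,
ultrastructural events, molecular interactions).

It is aimed at curators and bioinformaticians who want to encode
knowledge about cell states and transitions (reprogramming, EMT/MET,
trans-differentiation) in a computable form and then *do* something
with it: infer implied annotations, rank similar cell states or
transitions, derive mechanism changes from time-stamped phenotype
snapshots, and cluster fine-grained profiles into operational cell
types.

## The model

An annotation profile is a time-stamped set of EQ pairs
`(entity term, quality)`, e.g. the epithelial phenotype
`{(Occludin, present), (JAM, present), (Claudin, present),
(Tight junction, present), (Cell membrane, joined)}`, or the
mesenchymal–epithelial transition (MET) coded at mechanism level as
`{(Network for epithelial cell, up), (Network for mesenchymal cell, down)}`.

Ontology edges are `is_a` plus **all-some `has_part`**: “Tight junction
has_part Occludin” means every tight junction instance has some
Occludin as part. Because molecules are promiscuous (Occludin may serve
many structures) but wholes *necessitate* their parts, parthood runs
whole → part, which fixes the propagation calculus:

* a **positive** annotation (present/up/…) of *t* covers
  `positive_scope(t)`: everything reachable from *t* via
  `is_a` (subclass → superclass) and `has_part` (whole → part);
* **absent** covers `negative_scope(t)` — the contrapositive: if a
  necessary part is absent, so is every whole requiring it;
* **down** does not propagate in the default *sound* mode (a whole
  winding down does not entail each shared part winding down).

With counts taken on propagated corpora, information content
`IC(t) = −log₂(count(t)/N)` (bits) satisfies the ordering
IC(whole) ≥ IC(part). Term similarity is Resnik-style over the
propagation order — the most informative common propagation target —
and profiles are compared by symmetric best-match averaging (BMA) with
a quality-compatibility weight κ, or by simGIC (IC-weighted Jaccard).
Search is “BLAST in annotation space”: rank a corpus against a query
profile. Transitions are derived from pairs of phenotype profiles by
qualitative differential analysis through an explicit mechanism map
(marker and participant rules), inheriting start/end timestamps.
Clustering of the Lin-normalized BMA distance
`d = 1 − sim/√(sim_self·sim_self)` recovers coarse cell types and
transition classes.

## Worked example

Generate the example mechanism ontology and the mixed-granularity MET
profiles, compute information content, and search with a network-level
MET query:

```bash
ceq fixtures --what fig2 -o demo      # cell_mechanisms.obo
ceq fixtures --what fig4 -o demo      # met_profiles.tsv
ceq ic demo/met_profiles.tsv --onto demo/cell_mechanisms.obo -o demo/ic.tsv
ceq search demo/query.tsv --corpus demo/met_profiles.tsv \
    --onto demo/cell_mechanisms.obo -k 4
```

The IC table (excerpt) shows the whole-versus-part ordering: the
epithelial network is annotated once (2 bits) while its necessary
Occludin–JAM interaction accumulates three of four profiles
(−log₂(3/4) ≈ 0.415 bits):

```
term_id	count	ic_bits
CMM:0000001	1	2.000000
CMM:0000003	2	1.000000
CMM:0000006	3	0.415037
```

The search ranks the three MET profiles — curated at network, event and
interaction granularity, sharing *no* asserted annotation — above the
unrelated mesenchymal-shutdown control, because propagation lets them
meet at the interaction level:

```
rank	profile_id	score
1	met-network	1.083007
2	met-event	0.868383
3	met-interaction	0.332030
4	control-mesenchymal	0.000000
```

Deriving a transition from the example time series (`ceq transition
... --from cell-B --to cell-C`) yields the MET start-up
`{(Network for epithelial cell, up), (Network for tight junction, up),
(Interaction Occludin-JAM, up)}` with inherited timestamps
`start_h=1.0 end_h=2.0`.

## Layout

| module | contents |
|---|---|
| `celleq.onto` | terms, is_a / all-some has_part edges, scopes, OBO-subset I/O |
| `celleq.profiles` | qualities, EQ annotations, profiles, series, corpora, TSV I/O |
| `celleq.propagation` | polarity-aware sound/heuristic propagation |
| `celleq.similarity` | IC, Resnik term similarity, κ table, BMA, simGIC, search |
| `celleq.transitions` | mechanism maps, differential transition derivation |
| `celleq.clustering` | normalized distances, agglomerative clustering, ARI |
| `celleq.fixtures` | example ontologies/profiles, synthetic planted-cluster corpora |
| `celleq.cli` | the `ceq` command line |

See `docs/methods.md` for the modelling choices, defaults and known
limitations.
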