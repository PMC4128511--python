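"""Information content, Resnik/BMA/simGIC measures, similarity search."""

import math

import numpy as np
import pytest

from celleq.fixtures import (
    MECH,
    MET_PROFILE_IDS,
    random_corpus,
    random_ontology,
)
from celleq.profiles import Corpus, profile
from celleq.propagation import SOUND, propagate_corpus
from celleq.similarity import (
    default_compatibility,
    information_content,
    profile_similarity_bma,
    profile_similarity_simgic,
    quality_compatibility,
    similarity_search,
    term_similarity,
)


@pytest.fixture(scope="module")
def derived_corpus(mech_onto):
    """2 profiles start the epithelial programme, 1 the Occludin-JAM
    interaction alone, 1 shuts the mesenchymal programme down."""
    return Corpus((
        profile("e1", "mechanism-change", [(MECH["Network for epithelial cell"], "up")]),
        profile("e2", "mechanism-change", [(MECH["Network for epithelial cell"], "up")]),
        profile("i1", "mechanism-change", [(MECH["Interaction Occludin-JAM"], "up")]),
        profile("m1", "mechanism-change", [(MECH["Network for mesenchymal cell"], "down")]),
    ))


# conftest provides mech_onto at session scope; re-export at module scope for the fixture above
@pytest.fixture(scope="module")
def mech_onto():
    from celleq.fixtures import build_mechanism_fixture
    return build_mechanism_fixture()


class TestInformationContent:
    def test_hand_counted_bits(self, mech_onto, derived_corpus):
        ic = information_content(derived_corpus, mech_onto, SOUND)
        # whole programme: 2 of 4 profiles -> 1 bit; its necessary
        # interaction accumulates a third profile -> -log2(3/4)
        assert ic[MECH["Network for epithelial cell"]] == pytest.approx(1.0)
        assert ic[MECH["Interaction Occludin-JAM"]] == pytest.approx(-math.log2(3 / 4))
        assert ic.counts[MECH["Interaction Occludin-JAM"]] == 3
        # 'down' is negative polarity: it never feeds the counts
        assert ic.counts[MECH["Network for mesenchymal cell"]] == 0

    def test_universal_annotation_has_zero_ic(self, mech_onto):
        c = Corpus(tuple(
            profile(f"p{i}", "mechanism-change", [(MECH["S-phase"], "up")])
            for i in range(3)))
        ic = information_content(c, mech_onto, SOUND)
        assert ic[MECH["S-phase"]] == 0.0

    def test_unseen_terms_get_ic_max(self, mech_onto, derived_corpus):
        ic = information_content(derived_corpus, mech_onto, SOUND)
        assert ic[MECH["Mitosis"]] == pytest.approx(math.log2(4))
        assert ic.ic_max == pytest.approx(2.0)

    def test_bounds(self, mech_onto, derived_corpus):
        ic = information_content(derived_corpus, mech_onto, SOUND)
        for v in ic.ic.values():
            assert 0.0 <= v <= ic.ic_max

    def test_empty_corpus_rejected(self, mech_onto):
        with pytest.raises(ValueError):
            information_content(Corpus(()), mech_onto)

    @pytest.mark.parametrize("seed", range(10))
    def test_whole_has_higher_ic_than_parts(self, mech_onto, seed):
        # the IC ordering along has_part on random all-positive corpora
        rng = np.random.default_rng(1000 + seed)
        c = random_corpus(rng, mech_onto, n_profiles=int(rng.integers(2, 15)))
        ic = information_content(c, mech_onto, SOUND)
        for e in mech_onto.has_part_edges():
            assert ic[e.subject] >= ic[e.object] - 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_ic_antimonotone_along_positive_scope(self, seed):
        rng = np.random.default_rng(2000 + seed)
        o = random_ontology(rng, n_terms=20, kind="mechanism")
        c = random_corpus(rng, o, n_profiles=10)
        ic = information_content(c, o, SOUND)
        for t in o.terms:
            for s in o.positive_scope(t):
                assert ic[s] <= ic[t] + 1e-12


class TestTermSimilarity:
    def test_self_similarity_is_own_ic(self, mech_onto, derived_corpus):
        ic = information_content(derived_corpus, mech_onto, SOUND)
        for t in mech_onto.terms:
            assert term_similarity(t, t, ic, mech_onto) == pytest.approx(ic[t])

    def test_most_informative_common_target(self, mech_onto, derived_corpus):
        ic = information_content(derived_corpus, mech_onto, SOUND)
        s = term_similarity(MECH["Network for tight junction"],
                            MECH["Interaction Occludin-JAM"], ic, mech_onto)
        assert s == pytest.approx(-math.log2(3 / 4))

    def test_disjoint_components_score_zero(self, mech_onto, derived_corpus):
        ic = information_content(derived_corpus, mech_onto, SOUND)
        assert term_similarity(MECH["Mitosis"], MECH["Network for epithelial cell"],
                               ic, mech_onto) == 0.0

    def test_symmetry(self, mech_onto, derived_corpus):
        ic = information_content(derived_corpus, mech_onto, SOUND)
        terms = sorted(mech_onto.terms)
        for a in terms:
            for b in terms:
                assert term_similarity(a, b, ic, mech_onto) == term_similarity(b, a, ic, mech_onto)


class TestCompatibility:
    def test_diagonal_is_one(self, vocab, compat):
        for q in vocab:
            assert quality_compatibility(vocab.quality(q), vocab.quality(q), compat) == 1.0

    def test_cross_polarity_is_zero(self, vocab, compat):
        assert quality_compatibility(vocab.quality("up"), vocab.quality("down"), compat) == 0.0
        assert quality_compatibility(vocab.quality("present"), vocab.quality("absent"), compat) == 0.0

    def test_graded_up_pair(self, vocab, compat):
        assert quality_compatibility(vocab.quality("up"), vocab.quality("moderately_up"),
                                     compat) == 0.5

    def test_override_rejects_nonzero_cross_polarity(self, vocab):
        with pytest.raises(ValueError):
            default_compatibility(vocab, overrides={("up", "down"): 0.3})


def _bma_oracle(p1, p2, ic, tbl, o):
    """Naive double loop over all annotation pairs."""
    if not p1.annotations or not p2.annotations:
        return 0.0
    rows = []
    for a in p1.annotations:
        rows.append(max(tbl.kappa(a.quality, b.quality)
                        * term_similarity(a.entity, b.entity, ic, o)
                        for b in p2.annotations))
    cols = []
    for b in p2.annotations:
        cols.append(max(tbl.kappa(a.quality, b.quality)
                        * term_similarity(a.entity, b.entity, ic, o)
                        for a in p1.annotations))
    return (sum(rows) / len(rows) + sum(cols) / len(cols)) / 2


def _simgic_oracle(p1, p2, ic):
    s1 = {(a.entity, a.quality.polarity) for a in p1.annotations}
    s2 = {(a.entity, a.quality.polarity) for a in p2.annotations}
    if not (s1 | s2):
        return 0.0
    num = sum(ic[t] for t, _ in s1 & s2)
    den = sum(ic[t] for t, _ in s1 | s2)
    return num / den if den else len(s1 & s2) / len(s1 | s2)


class TestProfileSimilarity:
    def test_bma_self_similarity_is_mean_entity_ic(self, mech_onto, derived_corpus, compat):
        ic = information_content(derived_corpus, mech_onto, SOUND)
        p = profile("x", "mechanism-change", [(MECH["Network for epithelial cell"], "up"),
                                              (MECH["Mitosis"], "up")])
        expected = (ic[MECH["Network for epithelial cell"]] + ic[MECH["Mitosis"]]) / 2
        assert profile_similarity_bma(p, p, ic, compat, mech_onto) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_bma_matches_naive_oracle(self, mech_onto, compat, seed):
        rng = np.random.default_rng(3000 + seed)
        c = random_corpus(rng, mech_onto, n_profiles=6, positive_only=False)
        ic = information_content(c, mech_onto, SOUND)
        ps = list(c)
        for i in range(len(ps)):
            for j in range(len(ps)):
                got = profile_similarity_bma(ps[i], ps[j], ic, compat, mech_onto)
                want = _bma_oracle(ps[i], ps[j], ic, compat, mech_onto)
                assert got == pytest.approx(want)
                assert got >= 0.0

    def test_bma_empty_profile_scores_zero(self, mech_onto, derived_corpus, compat):
        ic = information_content(derived_corpus, mech_onto, SOUND)
        empty = profile("e", "mechanism-change", [])
        other = profile("o", "mechanism-change", [(MECH["Mitosis"], "up")])
        assert profile_similarity_bma(empty, other, ic, compat, mech_onto) == 0.0

    def test_bma_symmetric(self, mech_onto, compat):
        rng = np.random.default_rng(99)
        c = random_corpus(rng, mech_onto, n_profiles=6, positive_only=False)
        ic = information_content(c, mech_onto, SOUND)
        ps = list(c)
        for i in range(len(ps)):
            for j in range(len(ps)):
                assert (profile_similarity_bma(ps[i], ps[j], ic, compat, mech_onto)
                        == pytest.approx(profile_similarity_bma(ps[j], ps[i], ic, compat, mech_onto)))

    def test_kind_mismatch_rejected(self, mech_onto, derived_corpus, compat):
        ic = information_content(derived_corpus, mech_onto, SOUND)
        p1 = profile("a", "mechanism-change", [])
        p2 = profile("b", "phenotype", [])
        with pytest.raises(ValueError):
            profile_similarity_bma(p1, p2, ic, compat, mech_onto)

    def test_simgic_identity_and_disjoint(self, mech_onto, derived_corpus):
        ic = information_content(derived_corpus, mech_onto, SOUND)
        p = profile("a", "mechanism-change", [(MECH["Mitosis"], "up"), (MECH["S-phase"], "up")])
        q = profile("b", "mechanism-change", [(MECH["AJ formation"], "up")])
        assert profile_similarity_simgic(p, p, ic, mech_onto) == 1.0
        assert profile_similarity_simgic(p, q, ic, mech_onto) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_simgic_matches_set_arithmetic_oracle(self, mech_onto, seed):
        rng = np.random.default_rng(4000 + seed)
        c = random_corpus(rng, mech_onto, n_profiles=6, positive_only=False)
        ic = information_content(c, mech_onto, SOUND)
        ps = list(propagate_corpus(c, mech_onto, SOUND))
        for i in range(len(ps)):
            for j in range(len(ps)):
                got = profile_similarity_simgic(ps[i], ps[j], ic, mech_onto)
                assert got == pytest.approx(_simgic_oracle(ps[i], ps[j], ic))
                assert 0.0 <= got <= 1.0

    def test_simgic_never_decreased_by_propagation_for_nested_profiles(self, mech_onto,
                                                                       fig4_corpus):
        # profiles asserted within one another's scopes converge under propagation
        ic = information_content(fig4_corpus, mech_onto, SOUND)
        prop = propagate_corpus(fig4_corpus, mech_onto, SOUND)
        for i in range(3):
            for j in range(i + 1, 3):
                a, b = MET_PROFILE_IDS[i], MET_PROFILE_IDS[j]
                before = profile_similarity_simgic(fig4_corpus[a], fig4_corpus[b], ic, mech_onto)
                after = profile_similarity_simgic(prop[a], prop[b], ic, mech_onto)
                assert after >= before


class TestSearch:
    def test_corpus_member_query_ranks_itself_first(self, mech_onto, fig4_corpus, compat):
        # holds for profiles not nested inside a corpus-mate's propagation
        # scope; a strict superset profile can outscore the exact match
        ic = information_content(fig4_corpus, mech_onto, SOUND)
        res = similarity_search(fig4_corpus["met-interaction"], fig4_corpus, ic, compat,
                                mech_onto, k=4)
        assert res.ids()[0] == "met-interaction"

    def test_network_query_ranks_met_profiles_above_control(self, mech_onto, fig4_corpus,
                                                            compat):
        ic = information_content(fig4_corpus, mech_onto, SOUND)
        res = similarity_search(fig4_corpus["met-network"], fig4_corpus, ic, compat,
                                mech_onto, k=4)
        ranks = {pid: i for i, pid in enumerate(res.ids())}
        assert ranks["met-event"] < ranks["control-mesenchymal"]
        assert ranks["met-interaction"] < ranks["control-mesenchymal"]

    def test_k_zero_and_k_large(self, mech_onto, fig4_corpus, compat):
        ic = information_content(fig4_corpus, mech_onto, SOUND)
        q = fig4_corpus["met-network"]
        assert len(similarity_search(q, fig4_corpus, ic, compat, mech_onto, k=0)) == 0
        assert len(similarity_search(q, fig4_corpus, ic, compat, mech_onto, k=99)) == 4

    def test_deterministic_tiebreak_by_id(self, mech_onto, compat):
        c = Corpus((profile("b", "mechanism-change", [(MECH["Mitosis"], "up")]),
                    profile("a", "mechanism-change", [(MECH["Mitosis"], "up")])))
        ic = information_content(c, mech_onto, SOUND)
        q = profile("q", "mechanism-change", [(MECH["Mitosis"], "up")])
        res = similarity_search(q, c, ic, compat, mech_onto, k=2)
        assert res.ids() == ("a", "b")
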