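import numpy as np
import pytest

from celleq.fixtures import (
    build_figure4_profiles,
    build_mechanism_fixture,
    build_phenotype_fixture,
)
from celleq.profiles import DEFAULT_VOCABULARY
from celleq.similarity import default_compatibility


@pytest.fixture(scope="session")
def phen_onto():
    return build_phenotype_fixture()


@pytest.fixture(scope="session")
def mech_onto():
    return build_mechanism_fixture()


@pytest.fixture(scope="session")
def vocab():
    return DEFAULT_VOCABULARY


@pytest.fixture(scope="session")
def compat():
    return default_compatibility()


@pytest.fixture(scope="session")
def fig4_corpus():
    return build_figure4_profiles()


def fixpoint_scope(ontology, start, reverse=False):
    """Independent scope oracle: repeated edge relaxation to fixpoint.

    Forward direction follows is_a subclass->superclass and has_part
    whole->part, i.e. the direction a positive annotation covers.
    """
    pairs = [(e.subject, e.object) for e in ontology.edges]
    if reverse:
        pairs = [(b, a) for a, b in pairs]
    reach = {start}
    changed = True
    while changed:
        changed = False
        for a, b in pairs:
            if a in reach and b not in reach:
                reach.add(b)
                changed = True
    return frozenset(reach)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
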