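import pytest
from hypothesis import settings

from ontoslim.core import Ontology, Term
from ontoslim.synth import GeneratorParams, generate_ontology

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


def T(tid, name="", parents=(), roles=(), **kw):
    return Term(id=tid, name=name, is_a=tuple(parents), roles=tuple(roles), **kw)


@pytest.fixture
def chain3():
    """root -> g -> s, with s the only seed."""
    ont = Ontology(
        [
            T("X:root", "root"),
            T("X:g", "grouper", ["X:root"]),
            T("X:s", "seed", ["X:g"], is_seed_annotation=True),
        ]
    )
    return ont, frozenset(["X:s"])


@pytest.fixture
def diamond():
    """root -> {A, B} -> s."""
    ont = Ontology(
        [
            T("X:root", "root"),
            T("X:A", "alpha", ["X:root"]),
            T("X:B", "beta", ["X:root"]),
            T("X:s", "seed", ["X:A", "X:B"], is_seed_annotation=True),
        ]
    )
    return ont, frozenset(["X:s"])


@pytest.fixture
def taxonomy():
    """vertebrate -> bird -> owl: the textbook transitive-subclass example."""
    return Ontology(
        [
            T("X:vert", "vertebrate"),
            T("X:bird", "bird", ["X:vert"]),
            T("X:owl", "owl", ["X:bird"]),
        ]
    )


@pytest.fixture
def monosaccharide_shape():
    """A parent with 7 named grouping subclasses and 14 ungrouped seed leaves."""
    return make_monosaccharide_shape()


def make_monosaccharide_shape():
    terms = [
        T("X:root", "molecular entity"),
        T("X:mono", "monosaccharide", ["X:root"]),
    ]
    seeds = set()
    for i in range(7):
        gid = f"X:g{i}"
        terms.append(T(gid, f"grouping category {i}", ["X:mono"]))
        for j in range(2):
            sid = f"X:gs{i}_{j}"
            terms.append(T(sid, f"grouped sugar {i}.{j}", [gid], is_seed_annotation=True))
            seeds.add(sid)
    for k in range(14):
        sid = f"X:u{k:02d}"
        terms.append(T(sid, f"ungrouped sugar {k:02d}", ["X:mono"], is_seed_annotation=True))
        seeds.add(sid)
    return Ontology(terms), frozenset(seeds)


def small_params(rng_seed, **overrides):
    """Corpus member parameters: <= 60 terms, chains, roles, obsoletes."""
    kw = dict(
        n_grouping=25,
        n_seeds=10,
        max_chain_len=8,
        p_multiparent=0.2,
        n_roles=6,
        p_role_assertion=0.5,
        p_obsolete=0.05,
        rng_seed=rng_seed,
    )
    kw.update(overrides)
    return GeneratorParams(**kw)


def corpus(n, start=1, **overrides):
    """n generated (ontology, seeds) pairs, rng seeds start..start+n-1."""
    return [generate_ontology(small_params(s, **overrides)) for s in range(start, start + n)]
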