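"""Unit and property tests for the ontology model and graph queries."""

import networkx as nx
import pytest
from hypothesis import given, strategies as st

from ontoslim.core import (
    CycleError,
    InvalidCurieError,
    Ontology,
    StructuralError,
    Term,
    UnknownTermError,
    validate_curie,
)
from ontoslim.synth import legacy_chain_fixture

from _oracles import ancestors_oracle, closure, depth_oracle
from conftest import T, corpus


class TestCurie:
    @pytest.mark.parametrize("good", ["CHEBI:17552", "X:1", "OTHER:CHEBI_33282"])
    def test_accepts_wellformed(self, good):
        assert validate_curie(good) == good

    @pytest.mark.parametrize("bad", ["", "CHEBI", "CHEBI:", ":17552", "a:b:c", "a b:c"])
    def test_rejects_malformed(self, bad):
        with pytest.raises(InvalidCurieError):
            validate_curie(bad)


class TestTermInvariants:
    def test_obsolete_terms_carry_no_edges(self):
        t = Term(id="X:1", is_a=("X:2",), roles=("X:3",), obsolete=True)
        assert t.is_a == () and t.roles == ()

    def test_replaced_by_requires_obsolete(self):
        with pytest.raises(StructuralError):
            Term(id="X:1", replaced_by="X:2")

    def test_no_id_in_both_is_a_and_roles(self):
        with pytest.raises(StructuralError):
            Term(id="X:1", is_a=("X:2",), roles=("X:2",))


class TestParentsAndAncestors:
    def test_chain_parents(self, chain3):
        ont, _ = chain3
        assert ont.parents("X:s") == {"X:g"}
        assert ont.parents("X:root") == set()

    def test_diamond_parents(self, diamond):
        ont, _ = diamond
        assert ont.parents("X:s") == {"X:A", "X:B"}

    def test_subclass_transitivity_textbook_example(self, taxonomy):
        # an owl is a bird, and a bird is a vertebrate
        assert taxonomy.ancestors("X:owl") == {"X:bird", "X:vert"}
        assert taxonomy.ancestors("X:vert") == frozenset()

    def test_unknown_id_named_in_error(self, chain3):
        ont, _ = chain3
        with pytest.raises(UnknownTermError, match="X:nope"):
            ont.parents("X:nope")

    def test_ancestors_match_matrix_closure_on_random_dags(self):
        for ont, _seeds in corpus(10):
            cl = closure(ont)
            for term in ont:
                assert ont.ancestors(term.id) == ancestors_oracle(ont, term.id, cl)

    def test_ancestors_match_networkx(self):
        for ont, _seeds in corpus(5, start=30):
            g = nx.DiGraph()
            g.add_nodes_from(ont.ids())
            for t in ont:
                for p in t.is_a:
                    g.add_edge(t.id, p)  # edge child -> parent
            for t in ont:
                assert ont.ancestors(t.id) == nx.descendants(g, t.id)

    def test_ancestor_transitivity_property(self):
        for ont, _seeds in corpus(5, start=50):
            for t in ont:
                for b in ont.ancestors(t.id):
                    assert ont.ancestors(b) <= ont.ancestors(t.id)


class TestSourceBearingChildren:
    def test_chain(self, chain3):
        ont, seeds = chain3
        assert ont.source_bearing_children("X:g", seeds) == {"X:s"}
        assert ont.source_bearing_children("X:root", seeds) == {"X:g"}

    def test_only_branches_leading_to_seeds_count(self):
        ont = Ontology(
            [
                T("X:r", "r"),
                T("X:a", "a", ["X:r"]),
                T("X:b", "b", ["X:r"]),
                T("X:c", "c", ["X:r"]),
                T("X:s", "s", ["X:b"]),
            ]
        )
        assert ont.source_bearing_children("X:r", {"X:s"}) == {"X:b"}

    def test_empty_seed_set_is_vacuous(self, diamond):
        ont, _ = diamond
        for t in ont:
            assert ont.source_bearing_children(t.id, frozenset()) == frozenset()


class TestDepth:
    def test_root_is_depth_zero(self, chain3):
        ont, _ = chain3
        assert ont.depth("X:root") == 0

    def test_eighteen_level_grouping_chain_puts_seed_at_19(self):
        ont, seeds, _ = legacy_chain_fixture(18, 0)
        (seed,) = seeds
        assert ont.depth(seed, "shortest") == 19
        assert ont.depth(seed, "longest") == 19

    def test_shortcut_edge_changes_shortest_not_longest(self):
        base = [
            T("X:r", "r"),
            T("X:A", "A", ["X:r"]),
            T("X:B", "B", ["X:r"]),
            T("X:s", "s", ["X:A", "X:B"]),
        ]
        ont = Ontology(base)
        assert ont.depth("X:s", "shortest") == 2
        assert ont.depth("X:s", "longest") == 2
        shortcut = Ontology(
            [
                T("X:r", "r"),
                T("X:A", "A", ["X:r"]),
                T("X:B", "B", ["X:A"]),
                T("X:s", "s", ["X:B", "X:r"]),
            ]
        )
        assert shortcut.depth("X:s", "shortest") == 1
        assert shortcut.depth("X:s", "longest") == 3

    def test_depth_matches_path_enumeration_oracle(self):
        for ont, _seeds in corpus(8, start=10):
            for t in ont:
                if t.obsolete:
                    continue
                for mode in ("shortest", "longest"):
                    assert ont.depth(t.id, mode) == depth_oracle(ont, t.id, mode)

    def test_shortest_depth_recurrence(self):
        # d(t) = 1 + min over parents, for every non-root reachable term
        for ont, _seeds in corpus(4, start=20):
            roots = set(ont.roots)
            for t in ont:
                if t.obsolete or t.id in roots:
                    continue
                assert ont.depth(t.id) == 1 + min(ont.depth(p) for p in t.is_a)

    def test_shortest_never_exceeds_longest(self):
        for ont, _seeds in corpus(4, start=40):
            for t in ont:
                if not t.obsolete:
                    assert ont.depth(t.id, "shortest") <= ont.depth(t.id, "longest")

    def test_bad_mode_rejected(self, chain3):
        ont, _ = chain3
        with pytest.raises(ValueError):
            ont.depth("X:s", "average")


class TestMinimalTerms:
    def test_keeps_most_specific(self, taxonomy):
        assert taxonomy.minimal_terms({"X:bird", "X:owl"}) == {"X:owl"}

    def test_incomparable_terms_both_retained(self, diamond):
        ont, _ = diamond
        assert ont.minimal_terms({"X:A", "X:B"}) == {"X:A", "X:B"}

    def test_matches_pairwise_closure_filter(self):
        for ont, seeds in corpus(5, start=60):
            ids = sorted(ont.ids())[:6]
            cl = closure(ont)
            expected = {
                a
                for a in ids
                if not any(a in ancestors_oracle(ont, b, cl) for b in ids if b != a)
            }
            assert ont.minimal_terms(ids) == expected


class TestAcyclicity:
    def test_chain_passes(self, chain3):
        chain3[0].assert_acyclic()

    def test_two_cycle_reported_with_path(self):
        a = Term(id="X:A")
        b = Term(id="X:B", is_a=("X:A",))
        ont = Ontology([a, b], validate=False)
        ont["X:A"].is_a = ("X:B",)
        with pytest.raises(CycleError) as exc:
            ont.assert_acyclic()
        cycle = exc.value.cycle
        assert cycle[0] == cycle[-1] and set(cycle) == {"X:A", "X:B"}

    def test_back_edge_detected_like_dfs_oracle(self):
        for ont, _seeds in corpus(3, start=70):
            g = nx.DiGraph()
            g.add_nodes_from(ont.ids())
            for t in ont:
                for p in t.is_a:
                    g.add_edge(t.id, p)
            assert nx.is_directed_acyclic_graph(g)
            ont.assert_acyclic()  # agrees: no cycle
            # inject one back edge: make a root a child of a deep term
            deep = max(
                (t.id for t in ont if not t.obsolete), key=lambda i: ont.depth(i)
            )
            broken = ont.copy()
            broken[ont.roots[0]].is_a = (deep,)
            broken.invalidate()
            g.add_edge(ont.roots[0], deep)
            assert not nx.is_directed_acyclic_graph(g)
            with pytest.raises(CycleError):
                broken.assert_acyclic()


class TestMutators:
    def test_add_parent_refuses_cycle_and_rolls_back(self, taxonomy):
        with pytest.raises(CycleError):
            taxonomy.add_parent("X:vert", "X:owl")
        assert taxonomy.parents("X:vert") == set()

    def test_remove_term_splices_children_to_all_parents(self, diamond):
        ont, _ = diamond
        ont.remove_term("X:A")
        assert ont.parents("X:s") == {"X:B", "X:root"}

    @given(st.integers(min_value=1, max_value=12), st.integers(min_value=0, max_value=4))
    def test_roots_property_on_chains(self, n, extra_roots):
        terms = [T(f"X:{i}", f"t{i}", [f"X:{i-1}"] if i else []) for i in range(n)]
        terms += [T(f"X:r{j}", f"r{j}") for j in range(extra_roots)]
        ont = Ontology(terms)
        assert set(ont.roots) == {"X:0"} | {f"X:r{j}" for j in range(extra_roots)}
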