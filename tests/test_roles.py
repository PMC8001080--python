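"""Role materialization, gap reporting and the review-assignment loop."""

import pytest

from ontoslim.core import Ontology, StructuralError
from ontoslim.roles import (
    COMPOUND_SUBSET,
    MirrorConfig,
    NO_ROLE_SUBSET,
    RoleAssignmentError,
    apply_role_assignments,
    compound_id,
    direct_roles,
    inherited_roles,
    mirror_roles,
    parse_disposition,
    role_gap_report,
)

from conftest import T, corpus


@pytest.fixture
def penicillins():
    """Structure branch with roles: amoxicillin inherits via penicillin."""
    ont = Ontology(
        [
            T("X:chem", "chemical entity"),
            T("X:pen", "penicillin", ["X:chem"], roles=["R:abx"]),
            T("X:amox", "amoxicillin", ["X:pen"], is_seed_annotation=True),
            T("X:role", "role"),
            T("R:drug", "drug", ["X:role"]),
            T("R:abx", "antibacterial drug", ["R:drug"]),
        ]
    )
    return ont, frozenset(["X:amox"])


class TestDirectAndInherited:
    def test_asserted_role_is_direct(self, penicillins):
        ont, _ = penicillins
        assert direct_roles(ont, "X:pen") == {"R:abx"}
        assert direct_roles(ont, "X:amox") == frozenset()

    def test_roles_inherit_down_the_structure_tree(self, penicillins):
        ont, _ = penicillins
        assert inherited_roles(ont, "X:amox") == {"R:abx"}

    def test_role_hierarchy_not_closed_over(self, penicillins):
        # assertion-level union only: "drug" is reachable through the
        # mirrored compound edges, not through inherited_roles
        ont, _ = penicillins
        assert "R:drug" not in inherited_roles(ont, "X:amox")

    def test_roleless_root_has_none(self, chain3):
        ont, _ = chain3
        assert inherited_roles(ont, "X:root") == frozenset()

    def test_matches_closure_union_oracle(self):
        from _oracles import ancestors_oracle, closure

        for ont, seeds in corpus(5):
            cl = closure(ont)
            for s in seeds:
                expected = set(ont[s].roles)
                for anc in ancestors_oracle(ont, s, cl):
                    expected |= set(ont[anc].roles)
                assert inherited_roles(ont, s) == expected


class TestMirror:
    def cfg(self, root="X:chem"):
        return MirrorConfig(structural_root=root)

    def test_progesterone_under_hormone_compound(self):
        ont = Ontology(
            [
                T("X:chem", "chemical entity"),
                T("X:ster", "20-oxo-steroid", ["X:chem"]),
                T("X:prog", "progesterone", ["X:ster"], roles=["R:horm"],
                  is_seed_annotation=True),
                T("X:role", "role"),
                T("R:horm", "hormone", ["X:role"]),
            ]
        )
        mirrored, mapping = mirror_roles(ont, {"X:prog"}, self.cfg())
        cid, cname = mapping["R:horm"]
        assert cname == "hormone compound"
        assert cid in mirrored.parents("X:prog")
        # structural placement untouched
        assert "X:ster" in mirrored.parents("X:prog")
        # the compound branch tops out beside the structural root
        assert mirrored.parents(cid) == {"CPD:ROOT"}
        assert "CPD:ROOT" in mirrored.roots and "X:chem" in mirrored.roots

    def test_no_roles_yields_only_empty_top_term(self, chain3):
        ont, seeds = chain3
        cfg = MirrorConfig(structural_root="X:root")
        mirrored, mapping = mirror_roles(ont, seeds, cfg)
        assert mapping == {}
        assert mirrored.children("CPD:ROOT") == ()
        assert len(mirrored) == len(ont) + 1

    def test_minimal_placement_with_nested_roles(self, penicillins):
        ont, seeds = penicillins
        ont = ont.copy()
        # amoxicillin directly asserts the broader role too
        ont["X:amox"].roles = ("R:drug",)
        ont["X:amox"].normalize()
        mirrored, mapping = mirror_roles(ont, seeds, self.cfg())
        abx_c, drug_c = mapping["R:abx"][0], mapping["R:drug"][0]
        # attached under the most specific role compound only...
        assert abx_c in mirrored.parents("X:amox")
        assert drug_c not in mirrored.parents("X:amox")
        # ...but reachable from the broader compound via mirrored is_a
        assert drug_c in mirrored.ancestors("X:amox")
        assert mirrored.parents(abx_c) == {drug_c}

    def test_gap_between_in_use_roles_is_bridged(self):
        # seed uses only the deepest role; the middle role is not in use
        ont = Ontology(
            [
                T("X:chem", "chemical entity"),
                T("X:s", "s", ["X:chem"], roles=["R:c"], is_seed_annotation=True),
                T("X:role", "role"),
                T("R:a", "a", ["X:role"]),
                T("R:b", "b", ["R:a"]),
                T("R:c", "c", ["R:b"]),
            ]
        )
        mirrored, mapping = mirror_roles(ont, {"X:s"}, self.cfg())
        assert set(mapping) == {"R:c"}
        assert mirrored.parents(mapping["R:c"][0]) == {"CPD:ROOT"}

    def test_missing_structural_root_is_config_error(self, penicillins):
        ont, seeds = penicillins
        with pytest.raises(StructuralError):
            mirror_roles(ont, seeds, MirrorConfig())

    def test_idempotent(self, penicillins):
        ont, seeds = penicillins
        cfg = self.cfg()
        once, _ = mirror_roles(ont, seeds, cfg)
        twice, _ = mirror_roles(once, seeds, cfg)
        assert twice == once

    def test_compound_ids_deterministic(self):
        assert compound_id("CHEBI:33282") == "CPD:CHEBI_33282"

    def test_name_override(self, penicillins):
        ont, seeds = penicillins
        cfg = MirrorConfig(
            structural_root="X:chem",
            name_overrides={"R:abx": "antibacterial drug"},
        )
        _, mapping = mirror_roles(ont, seeds, cfg)
        assert mapping["R:abx"][1] == "antibacterial drug"


@pytest.fixture
def gap_fixture():
    """4 roleless seeds only under "other" buckets; 9 roleless elsewhere; 2 with roles."""
    terms = [
        T("X:chem", "chemical entity"),
        T("X:grp", "named group", ["X:chem"]),
        T("X:oth", "other chemical entity", ["X:chem"]),
        T("X:role", "role"),
        T("R:r1", "some role", ["X:role"]),
    ]
    seeds = set()
    for i in range(4):
        sid = f"X:o{i}"
        terms.append(T(sid, f"orphan {i}", ["X:oth"], is_seed_annotation=True))
        seeds.add(sid)
    for i in range(9):
        sid = f"X:p{i}"
        terms.append(T(sid, f"placed {i}", ["X:grp"], is_seed_annotation=True))
        seeds.add(sid)
    for i in range(2):
        sid = f"X:w{i}"
        terms.append(
            T(sid, f"with role {i}", ["X:grp"], roles=["R:r1"], is_seed_annotation=True)
        )
        seeds.add(sid)
    return Ontology(terms), frozenset(seeds)


class TestGapReport:
    def test_two_pass_counts(self, gap_fixture):
        ont, seeds = gap_fixture
        other_only = role_gap_report(ont, seeds, "other_only")
        everything = role_gap_report(ont, seeds, "all")
        assert len(other_only) == 4
        assert len(everything) == 13
        assert {r.term_id for r in other_only} <= {r.term_id for r in everything}

    def test_inherited_role_excludes_from_both_modes(self, penicillins):
        ont, seeds = penicillins
        assert role_gap_report(ont, seeds, "all") == []
        assert role_gap_report(ont, seeds, "other_only") == []

    def test_matches_set_difference_oracle(self, gap_fixture):
        ont, seeds = gap_fixture
        roleless = {s for s in seeds if not inherited_roles(ont, s)}
        assert {r.term_id for r in role_gap_report(ont, seeds, "all")} == roleless
        under_other = {
            s
            for s in roleless
            if all(
                ont[p].name.startswith("other ")
                for p in ont.parents(s)
            )
        }
        assert {
            r.term_id for r in role_gap_report(ont, seeds, "other_only")
        } == under_other

    def test_row_carries_spreadsheet_columns(self, gap_fixture):
        ont, seeds = gap_fixture
        row = role_gap_report(ont, seeds, "all")[0]
        assert row.term_id in seeds
        assert row.term_id in row.link
        assert row.assigned_disposition == "unreviewed"
        assert row.parents


class TestApplyAssignments:
    def test_disposition_grammar(self):
        assert parse_disposition("NR") == ("nr", {})
        assert parse_disposition("CHEBI:33282") == ("role", {"role": "CHEBI:33282"})
        kind, info = parse_disposition("NEW:pesticide|R:app")
        assert kind == "new" and info == {"name": "pesticide", "parent": "R:app"}
        with pytest.raises(RoleAssignmentError):
            parse_disposition("no idea")

    def test_nr_removes_from_future_gap_reports(self, gap_fixture):
        ont, seeds = gap_fixture
        out, summary = apply_role_assignments(ont, [("X:o0", "NR")], "X:role")
        assert summary.nr == 1
        assert NO_ROLE_SUBSET in out["X:o0"].subsets
        assert "X:o0" not in {r.term_id for r in role_gap_report(out, seeds, "all")}

    def test_new_role_created_under_named_branch(self, gap_fixture):
        ont, seeds = gap_fixture
        out, summary = apply_role_assignments(
            ont, [("X:p0", "NEW:pesticide|X:role")], "X:role"
        )
        assert summary.created == 1 and summary.assigned == 1
        (rid,) = out["X:p0"].roles
        assert out[rid].name == "pesticide"
        assert out.parents(rid) == {"X:role"}

    def test_new_parent_outside_role_branch_rejected(self, gap_fixture):
        ont, _ = gap_fixture
        with pytest.raises(RoleAssignmentError, match="role branch"):
            apply_role_assignments(ont, [("X:p0", "NEW:dye|X:grp")], "X:role")

    def test_unknown_role_id_rejected(self, gap_fixture):
        ont, _ = gap_fixture
        with pytest.raises(RoleAssignmentError, match="unknown role"):
            apply_role_assignments(ont, [("X:p0", "R:nope")], "X:role")

    def test_conflicting_duplicate_rows_rejected(self, gap_fixture):
        ont, _ = gap_fixture
        with pytest.raises(RoleAssignmentError, match="conflicting"):
            apply_role_assignments(
                ont, [("X:p0", "NR"), ("X:p0", "R:r1")], "X:role"
            )

    def test_empty_rows_are_identity(self, gap_fixture):
        ont, _ = gap_fixture
        out, summary = apply_role_assignments(ont, [], "X:role")
        assert out == ont
        assert (summary.nr, summary.assigned, summary.created) == (0, 0, 0)

    def test_full_review_empties_the_report(self, gap_fixture):
        ont, seeds = gap_fixture
        rows = []
        for i, gap in enumerate(role_gap_report(ont, seeds, "all")):
            if i % 3 == 0:
                rows.append((gap.term_id, "NR"))
            elif i % 3 == 1:
                rows.append((gap.term_id, "R:r1"))
            else:
                rows.append((gap.term_id, "NEW:industrial reagent|X:role"))
        out, _ = apply_role_assignments(ont, rows, "X:role")
        assert role_gap_report(out, seeds, "all") == []


class TestMirrorInvariants:
    def test_completeness_and_complementarity_on_corpus(self):
        for ont, seeds in corpus(6, start=80):
            cfg = MirrorConfig(structural_root="SYN:0000001")
            mirrored, _ = mirror_roles(ont, seeds, cfg)
            below_top = mirrored.descendants("CPD:ROOT")
            gaps = {r.term_id for r in role_gap_report(mirrored, seeds, "all")}
            for s in seeds:
                if inherited_roles(ont, s):
                    assert s in below_top and s not in gaps
                else:
                    assert s not in below_top and s in gaps

    def test_no_seed_under_two_comparable_compounds(self):
        for ont, seeds in corpus(6, start=90):
            mirrored, mapping = mirror_roles(
                ont, seeds, MirrorConfig(structural_root="SYN:0000001")
            )
            rev = {cid: role for role, (cid, _n) in mapping.items()}
            for s in seeds:
                croles = [
                    rev[p] for p in mirrored.parents(s) if p in rev
                ]
                for a in croles:
                    for b in croles:
                        assert a == b or a not in ont.ancestors(b)
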