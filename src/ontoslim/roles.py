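"""Materializing "has role" assertions into a browsable compound hierarchy.

Chemical classifications assert functions through existential axioms
("amoxicillin has_role some antibacterial drug"). Those anonymous parents
are invisible to a tree browser. This module builds a "chemical entity by
role" branch next to the structural root: each role that is actually in use
by a curated seed gets a generated compound class ("hormone" -> "hormone
compound"), compound subclass edges mirror the in-use fragment of the role
hierarchy, and every seed is attached under the compounds of its *minimal*
inherited roles — deeper roles imply the broader ones through the mirrored
edges, so nothing is double-placed.

The same machinery drives the curation loop: gap reports list seeds with no
inherited role at all, and reviewed assignment rows (existing role, newly
minted role, or "NR" for deliberately role-less compounds) feed back into
the ontology.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .core import Ontology, OntologyError, StructuralError, Term
from .render import is_other_name

__all__ = [
    "MirrorConfig",
    "RoleGapRow",
    "AssignmentSummary",
    "RoleAssignmentError",
    "direct_roles",
    "inherited_roles",
    "mirror_roles",
    "role_gap_report",
    "apply_role_assignments",
    "parse_disposition",
    "COMPOUND_SUBSET",
    "NO_ROLE_SUBSET",
    "GAP_COLUMNS",
]

log = logging.getLogger(__name__)

COMPOUND_SUBSET = "role_compound"
#: Persistent annotation for reviewed no-role compounds (kept across releases).
NO_ROLE_SUBSET = "no_role"

GAP_COLUMNS = ("term_id", "link", "name", "parents", "assigned_disposition")


class RoleAssignmentError(OntologyError):
    pass


@dataclass(frozen=True)
class MirrorConfig:
    """Configuration for compound-hierarchy generation.

    ``structural_root`` must name the "chemical entity"-like root; the
    generated top term becomes its sibling. Compound names follow
    ``name_template`` unless overridden per role (curators sometimes prefer
    the bare role name, e.g. "antibacterial drug").
    """

    structural_root: str = ""
    top_id: str = "CPD:ROOT"
    top_name: str = "chemical entity by role"
    compound_prefix: str = "CPD"
    name_template: str = "{role} compound"
    name_overrides: dict = field(default_factory=dict)


def direct_roles(ontology: Ontology, term_id: str) -> frozenset[str]:
    """Role targets asserted on the term itself."""
    return frozenset(ontology[term_id].roles)


def inherited_roles(ontology: Ontology, term_id: str) -> frozenset[str]:
    """Union of direct roles over the term and its structural ancestors.

    Assertion-level union only: ancestors *in the role hierarchy* of an
    asserted role are not added here — browsing reaches them through the
    mirrored compound is_a edges instead.
    """
    roles = set(ontology[term_id].roles)
    for anc in ontology.ancestors(term_id):
        roles.update(ontology[anc].roles)
    return frozenset(roles)


def compound_id(role_id: str, prefix: str = "CPD") -> str:
    """Deterministic compound id derived from the role id."""
    return f"{prefix}:{role_id.replace(':', '_')}"


def mirror_roles(
    ontology: Ontology,
    seeds: Iterable[str],
    config: Optional[MirrorConfig] = None,
) -> tuple[Ontology, dict[str, tuple[str, str]]]:
    """Generate the "chemical entity by role" branch.

    Returns the augmented ontology and the role -> (compound id, compound
    name) map. Idempotent: running on an already-mirrored ontology changes
    nothing, because compound ids are deterministic functions of role ids
    and attachments are recomputed to the same sets.
    """
    config = config or MirrorConfig()
    if not config.structural_root:
        raise StructuralError("mirror_roles requires a designated structural root")
    if config.structural_root not in ontology:
        raise StructuralError(
            f"structural root {config.structural_root} not in ontology"
        )
    seeds = frozenset(seeds)
    work = ontology.copy()

    in_use: set[str] = set()
    seed_roles: dict[str, frozenset[str]] = {}
    for seed in sorted(seeds):
        roles = inherited_roles(work, seed)
        seed_roles[seed] = roles
        in_use |= roles

    # top term: sibling of the structural root (i.e. itself a root)
    if config.top_id not in work:
        work.add_term(
            Term(
                id=config.top_id,
                name=config.top_name,
                subsets=(COMPOUND_SUBSET,),
            )
        )

    mapping: dict[str, tuple[str, str]] = {}
    for role in sorted(in_use):
        cid = compound_id(role, config.compound_prefix)
        name = config.name_overrides.get(
            role, config.name_template.format(role=work[role].name)
        )
        mapping[role] = (cid, name)
        if cid not in work:
            work.add_term(Term(id=cid, name=name, subsets=(COMPOUND_SUBSET,)))
        else:
            work[cid].name = name
            work.invalidate()

    # compound is_a edges mirror role is_a edges restricted to in-use roles;
    # roles whose in-use ancestors are deeper bridge to the nearest in-use
    # ancestor compound, else to the top term
    for role in sorted(in_use):
        cid = mapping[role][0]
        in_use_ancestors = ontology.ancestors(role) & in_use
        nearest = work.minimal_terms(in_use_ancestors)
        parents = sorted(mapping[a][0] for a in nearest) or [config.top_id]
        work.set_parents(cid, parents)

    # attach each seed under its minimal inherited roles only
    for seed in sorted(seeds):
        roles = seed_roles[seed]
        if not roles:
            continue
        minimal = work.minimal_terms(roles)
        term = work[seed]
        wanted = {mapping[r][0] for r in minimal}
        existing_compound_parents = {
            p for p in term.is_a if COMPOUND_SUBSET in work[p].subsets
        }
        structural = [p for p in term.is_a if p not in existing_compound_parents]
        term.is_a = tuple(structural) + tuple(sorted(wanted))
        term.normalize()
        work.invalidate()

    work.validate()
    return work, mapping


def structural_parents(ontology: Ontology, term_id: str) -> tuple[str, ...]:
    """is_a parents excluding generated compound classes."""
    return tuple(
        p
        for p in ontology[term_id].is_a
        if COMPOUND_SUBSET not in ontology[p].subsets
    )


@dataclass(frozen=True)
class RoleGapRow:
    term_id: str
    link: str
    name: str
    parents: str
    assigned_disposition: str = "unreviewed"

    def as_mapping(self) -> dict:
        return {
            "term_id": self.term_id,
            "link": self.link,
            "name": self.name,
            "parents": self.parents,
            "assigned_disposition": self.assigned_disposition,
        }


DEFAULT_LINK_TEMPLATE = "https://www.iedb.org/epitope/{id}"


def role_gap_report(
    ontology: Ontology,
    seeds: Iterable[str],
    mode: str = "all",
    link_template: str = DEFAULT_LINK_TEMPLATE,
) -> list[RoleGapRow]:
    """Curated terms with no inherited role, as reviewable spreadsheet rows.

    ``mode="other_only"`` restricts to seeds whose every structural parent
    is an "other ..." bucket — the poorly-placed compounds reviewed first in
    the curation loop. Terms already reviewed as NR are excluded. Rows sort
    by (name, id).
    """
    if mode not in ("all", "other_only"):
        raise ValueError(f"mode must be all|other_only, got {mode!r}")
    rows: list[RoleGapRow] = []
    for seed in sorted(set(seeds)):
        term = ontology[seed]
        if NO_ROLE_SUBSET in term.subsets:
            continue
        if inherited_roles(ontology, seed):
            continue
        parents = structural_parents(ontology, seed)
        if mode == "other_only":
            if not parents or not all(
                is_other_name(ontology[p].name) for p in parents
            ):
                continue
        rows.append(
            RoleGapRow(
                term_id=seed,
                link=link_template.format(id=seed),
                name=term.name,
                parents="; ".join(sorted(ontology[p].name for p in parents)),
            )
        )
    rows.sort(key=lambda r: (r.name, r.term_id))
    return rows


@dataclass
class AssignmentSummary:
    nr: int = 0
    assigned: int = 0
    created: int = 0


_NEW_RE = re.compile(r"^NEW:(?P<name>[^|]+)\|(?P<parent>\S+)$")


def parse_disposition(text: str) -> tuple[str, dict]:
    """Parse an assignment disposition: "NR" | CURIE | "NEW:name|parentCURIE"."""
    text = text.strip()
    if text == "NR":
        return "nr", {}
    m = _NEW_RE.match(text)
    if m:
        return "new", {"name": m.group("name").strip(), "parent": m.group("parent")}
    if ":" in text and " " not in text:
        return "role", {"role": text}
    raise RoleAssignmentError(f"cannot parse disposition: {text!r}")


def _role_slug(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9]+", "_", name.strip().lower()).strip("_")


def _in_role_branch(ontology: Ontology, role_id: str, role_root: str) -> bool:
    return role_id == role_root or role_root in ontology.ancestors(role_id)


def apply_role_assignments(
    ontology: Ontology,
    rows: Iterable[tuple[str, str]],
    role_root: str,
    new_role_prefix: str = "ROLE",
) -> tuple[Ontology, AssignmentSummary]:
    """Ingest reviewed (term id, disposition) pairs.

    NR rows persist a no-role annotation so future gap reports skip the
    term; existing-role rows add the has_role assertion; NEW rows mint a
    role (deterministic id from the name) under the given parent, which
    must lie inside the role branch. Conflicting duplicate rows for one
    term are an error.
    """
    if role_root not in ontology:
        raise RoleAssignmentError(f"role root {role_root} not in ontology")
    work = ontology.copy()
    summary = AssignmentSummary()
    seen: dict[str, str] = {}
    for term_id, disposition in rows:
        if term_id not in work:
            raise RoleAssignmentError(f"unknown term in assignments: {term_id}")
        if term_id in seen and seen[term_id] != disposition:
            raise RoleAssignmentError(
                f"conflicting dispositions for {term_id}: "
                f"{seen[term_id]!r} vs {disposition!r}"
            )
        if term_id in seen:
            continue
        seen[term_id] = disposition
        kind, info = parse_disposition(disposition)
        term = work[term_id]
        if kind == "nr":
            if NO_ROLE_SUBSET not in term.subsets:
                term.subsets = (*term.subsets, NO_ROLE_SUBSET)
                term.normalize()
            summary.nr += 1
        elif kind == "role":
            role_id = info["role"]
            if role_id not in work:
                raise RoleAssignmentError(f"unknown role id: {role_id}")
            if not _in_role_branch(work, role_id, role_root):
                raise RoleAssignmentError(
                    f"{role_id} is not inside the role branch ({role_root})"
                )
            term.roles = (*term.roles, role_id)
            term.normalize()
            work.invalidate()
            summary.assigned += 1
        else:  # new role
            parent = info["parent"]
            if parent not in work:
                raise RoleAssignmentError(f"unknown NEW parent role: {parent}")
            if not _in_role_branch(work, parent, role_root):
                raise RoleAssignmentError(
                    f"NEW parent {parent} is outside the role branch ({role_root})"
                )
            role_id = f"{new_role_prefix}:{_role_slug(info['name'])}"
            if role_id in work:
                if work[role_id].name != info["name"]:
                    raise RoleAssignmentError(
                        f"minted role id {role_id} collides with existing term "
                        f"{work[role_id].name!r}"
                    )
            else:
                work.add_term(Term(id=role_id, name=info["name"], is_a=(parent,)))
                summary.created += 1
            term.roles = (*term.roles, role_id)
            term.normalize()
            work.invalidate()
            summary.assigned += 1
    return work, summary
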