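"""The structure-tree slimming pipeline.

Stages, in the order :func:`slim` composes them:

1. :func:`extract_subset` — keep only the curated seed terms, their
   ancestors, and the roles those terms carry (with the roles' ancestors).
2. :func:`prune_chains` — repeatedly splice out uncurated grouping classes
   that organize almost nothing: a deep ChEBI-style chain of single-child
   grouping classes collapses so a seed once 19 levels down sits directly
   under the root (or under explicitly protected checkpoint classes).
3. :func:`make_other_buckets` — collect leaf entries that fit none of a
   parent's named subcategories into a synthesized "other {parent}" class,
   so sparse stragglers do not clutter the branch.
4. :func:`apply_edit_script` — replay recorded manual curation steps.
5. :func:`duplicate_placement_report` — flag terms placed under several
   branches at a given level, minus reviewed exceptions.

Splicing always re-attaches orphaned children to *all* parents of the
removed class, so every browse path in the multi-parent graph survives, and
seed terms are never removed by any stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .core import (
    CycleError,
    Ontology,
    StructuralError,
    Term,
    UnknownTermError,
)
from .editscript import EditScript, EditScriptError
from .render import is_other_name, render_tree, to_indented_text

__all__ = [
    "PruneConfig",
    "PruneRecord",
    "PruneLog",
    "SlimResult",
    "extract_subset",
    "prune_chains",
    "make_other_buckets",
    "apply_edit_script",
    "duplicate_placement_report",
    "slim",
]

log = logging.getLogger(__name__)

#: Subset tag stamped on synthesized "other" buckets.
BUCKET_SUBSET = "other_bucket"


@dataclass(frozen=True)
class PruneConfig:
    """Thresholds steering automatic pruning and bucket synthesis.

    ``max_spliceable_children``: an uncurated grouping class is spliced out
    when its count of source-bearing children (children leading to at least
    one seed) is at or below this; 1 removes single-lineage chains while
    keeping genuinely branching groupers. ``count_mode`` may be set to
    ``all_children`` to count raw children instead. ``other_bucket_min`` is
    the minimum number of ungrouped leaf entries under a parent before an
    "other" bucket is worth creating. ``protected`` ids are never removed.
    """

    max_spliceable_children: int = 1
    other_bucket_min: int = 3
    protected: frozenset[str] = frozenset()
    level_cap_for_duplicates: int = 2
    count_mode: str = "source_bearing"  # or "all_children"
    bucket_prefix: str = "OTHER"

    def __post_init__(self) -> None:
        if self.max_spliceable_children < 0:
            raise ValueError("max_spliceable_children must be >= 0")
        if self.other_bucket_min < 1:
            raise ValueError("other_bucket_min must be >= 1")
        if self.count_mode not in ("source_bearing", "all_children"):
            raise ValueError(f"bad count_mode: {self.count_mode!r}")
        object.__setattr__(self, "protected", frozenset(self.protected))


@dataclass(frozen=True)
class PruneRecord:
    removed: str
    parents: tuple[str, ...]
    children: tuple[str, ...]


PruneLog = list


def _check_seeds(ontology: Ontology, seeds: Iterable[str]) -> frozenset[str]:
    seeds = frozenset(seeds)
    missing = sorted(s for s in seeds if s not in ontology)
    if missing:
        raise StructuralError(f"unresolvable seed ids: {missing}")
    return seeds


def extract_subset(ontology: Ontology, seeds: Iterable[str]) -> Ontology:
    """Seed-closure module extraction.

    Retains seeds, their ancestors, every role referenced by a retained
    term, and those roles' ancestors; all references are restricted to the
    retained set. Obsolete terms are never retained, and obsolete seeds are
    an error (a seed must survive every transformation).
    """
    seeds = _check_seeds(ontology, seeds)
    if not seeds:
        raise StructuralError("extract_subset requires a non-empty seed set")
    dead = sorted(s for s in seeds if ontology[s].obsolete)
    if dead:
        raise StructuralError(f"seeds are obsolete terms: {dead}")

    retained: set[str] = set()
    for seed in seeds:
        retained.add(seed)
        retained |= ontology.ancestors(seed)
    roles = {
        r for tid in retained for r in ontology[tid].roles
    }
    for role in roles:
        retained.add(role)
        retained |= ontology.ancestors(role)
    retained = {tid for tid in retained if not ontology[tid].obsolete}

    new_terms = []
    for tid in sorted(retained):
        term = ontology[tid].copy()
        term.is_a = tuple(p for p in term.is_a if p in retained)
        term.roles = tuple(r for r in term.roles if r in retained)
        term.is_seed_annotation = tid in seeds
        term.normalize()
        new_terms.append(term)
    return Ontology(new_terms)


def _splice_count(
    ontology: Ontology, term_id: str, seeds: frozenset[str], config: PruneConfig
) -> int:
    if config.count_mode == "all_children":
        return len(ontology.children(term_id))
    return len(ontology.source_bearing_children(term_id, seeds))


def prune_chains(
    ontology: Ontology,
    seeds: Iterable[str],
    config: Optional[PruneConfig] = None,
) -> tuple[Ontology, list[PruneRecord]]:
    """Iteratively splice out low-value grouping classes, to fixpoint.

    A term is spliced when it is a grouping class over at least one seed
    (pruning is a structure-tree operation: role-hierarchy terms and
    seedless branches are never candidates), is not itself a seed,
    protected, or a root, and its (source-bearing) child count is at or
    below ``max_spliceable_children``. Children re-attach to all parents of
    the removed class — so seed-to-seed ancestry through surviving classes
    is preserved and no seed ever gets deeper — and the removed class's
    role assertions transfer onto them, so no seed loses an inherited role.
    """
    config = config or PruneConfig()
    seeds = _check_seeds(ontology, seeds)
    work = ontology.copy()
    protected = set(config.protected)
    log_records: list[PruneRecord] = []

    while True:
        candidates = sorted(
            (t.id for t in work), key=lambda tid: (work[tid].name, tid)
        )
        removed_any = False
        root_set = set(work.roots)
        for tid in candidates:
            term = work[tid]
            if (
                term.obsolete
                or tid in seeds
                or tid in protected
                or tid in root_set
            ):
                continue
            if not (work.descendants(tid) & seeds):
                continue  # no seed below: not a structure-tree grouping class
            if _splice_count(work, tid, seeds, config) > config.max_spliceable_children:
                continue
            record = PruneRecord(
                removed=tid,
                parents=tuple(sorted(work.parents(tid))),
                children=tuple(sorted(work.children(tid))),
            )
            work.remove_term(tid, splice=True, transfer_roles=True)
            log_records.append(record)
            removed_any = True
            break  # re-evaluate counts from scratch after each removal
        if not removed_any:
            return work, log_records


def _is_bucket(term: Term) -> bool:
    return BUCKET_SUBSET in term.subsets or is_other_name(term.name)


def mint_bucket_id(parent_id: str, prefix: str = "OTHER") -> str:
    """Deterministic bucket id in a dedicated namespace, derived from the parent."""
    return f"{prefix}:{parent_id.replace(':', '_')}"


def make_other_buckets(
    ontology: Ontology,
    seeds: Iterable[str],
    config: Optional[PruneConfig] = None,
) -> Ontology:
    """Synthesize "other {parent}" classes for ungrouped leaf entries.

    A parent qualifies when it has at least one named (non-seed, non-leaf)
    grouping child and at least ``other_bucket_min`` direct children that
    are seeds or leaves with no grouping-class placement under the same
    parent. Buckets never nest, reuse an existing "other ..." sibling
    instead of colliding, and the operation is idempotent. Only parents
    with seed descendants are considered — the role hierarchy and mirrored
    compound branch never grow buckets.
    """
    config = config or PruneConfig()
    seeds = _check_seeds(ontology, seeds)
    work = ontology.copy()

    for pid in list(work.ids()):
        if pid not in work:  # removed? (not expected, defensive)
            continue
        parent = work[pid]
        if parent.obsolete or _is_bucket(parent) or "role_compound" in parent.subsets:
            continue
        if not (set(work.descendants(pid)) & seeds):
            continue
        children = work.children(pid)
        grouping = [
            c
            for c in children
            if c not in seeds and work.children(c)
        ]
        if not grouping:
            continue
        below = set(work.descendants(pid))

        def grouped_elsewhere(cid: str) -> bool:
            for other_parent in work.parents(cid):
                if other_parent == pid:
                    continue
                if other_parent in below and other_parent not in seeds:
                    return True
            return False

        ungrouped = [
            c
            for c in children
            if (c in seeds or not work.children(c))
            and not _is_bucket(work[c])
            and not grouped_elsewhere(c)
        ]
        if len(ungrouped) < config.other_bucket_min:
            continue

        bucket_name = f"other {parent.name}".strip()
        existing = [
            c for c in children if work[c].name == bucket_name
        ]
        if existing:
            bucket_id = existing[0]
            log.info("reusing existing bucket %s under %s", bucket_id, pid)
            bucket = work[bucket_id]
            if BUCKET_SUBSET not in bucket.subsets:
                bucket.subsets = (*bucket.subsets, BUCKET_SUBSET)
                bucket.normalize()
        else:
            bucket_id = mint_bucket_id(pid, config.bucket_prefix)
            if bucket_id in work:
                bucket_id_base = bucket_id
                n = 2
                while bucket_id in work:
                    bucket_id = f"{bucket_id_base}_{n}"
                    n += 1
            work.add_term(
                Term(
                    id=bucket_id,
                    name=bucket_name,
                    is_a=(pid,),
                    subsets=(BUCKET_SUBSET,),
                )
            )
        for cid in sorted(ungrouped):
            work.remove_parent(cid, pid)
            if bucket_id not in work.parents(cid):
                work.add_parent(cid, bucket_id)
    return work


# ---------------------------------------------------------------------------
# Edit-script application


def _resolve_target(ontology: Ontology, target: str, step_idx: int) -> str:
    """Resolve a step target given as id or (unique) name."""
    if target in ontology:
        return target
    matches = [t.id for t in ontology if t.name == target]
    if len(matches) == 1:
        return matches[0]
    if not matches:
        raise EditScriptError(f"step {step_idx}: unresolvable target {target!r}")
    raise EditScriptError(
        f"step {step_idx}: ambiguous target name {target!r} -> {matches}"
    )


def _as_id_list(value) -> list[str]:
    if value is None:
        return []
    if isinstance(value, str):
        return [value]
    return [str(v) for v in value]


def apply_edit_script(
    ontology: Ontology,
    script: EditScript,
    seeds: frozenset[str] = frozenset(),
) -> Ontology:
    """Apply an edit script step by step, preserving all model invariants.

    Steps apply strictly in order; each step's targets must resolve at its
    application time. Any step that would remove a seed term or create an
    is_a cycle raises, naming the step index (and the cycle path).
    """
    work = ontology.copy()
    for idx, step in enumerate(script):
        try:
            _apply_step(work, step, idx, seeds)
        except (CycleError, UnknownTermError) as exc:
            raise EditScriptError(f"step {idx} ({step.op}): {exc}") from exc
    work.validate()
    return work


def _apply_step(work: Ontology, step, idx: int, seeds: frozenset[str]) -> None:
    op = step.op
    args = step.args
    if op == "create_class":
        new_id = step.target
        if new_id in work:
            raise EditScriptError(f"step {idx}: id {new_id} already exists")
        parents = [
            _resolve_target(work, p, idx) for p in _as_id_list(args.get("parents"))
        ]
        work.add_term(
            Term(id=new_id, name=str(args.get("name", "")), is_a=tuple(parents))
        )
        return

    target = _resolve_target(work, step.target, idx)

    if op == "rename":
        if "new_name" not in args:
            raise EditScriptError(f"step {idx}: rename requires new_name")
        work[target].name = str(args["new_name"])
        work.invalidate()
    elif op in ("remove_class", "splice_class"):
        if target in seeds:
            raise EditScriptError(f"step {idx}: refusing to remove seed {target}")
        work.remove_term(target, splice=True)
    elif op == "add_parent":
        parent = _resolve_target(work, str(args["parent"]), idx)
        work.add_parent(target, parent)
    elif op == "remove_parent":
        parent = _resolve_target(work, str(args["parent"]), idx)
        work.remove_parent(target, parent)
    elif op == "move_term":
        if "new_parents" in args:
            parents = [
                _resolve_target(work, p, idx)
                for p in _as_id_list(args["new_parents"])
            ]
            work.set_parents(target, parents)
        else:
            add = _as_id_list(args.get("add_parents") or args.get("add_parent"))
            rem = _as_id_list(
                args.get("remove_parents") or args.get("remove_parent")
            )
            if not add and not rem:
                raise EditScriptError(
                    f"step {idx}: move_term requires new_parents or add/remove parents"
                )
            for p in add:
                work.add_parent(target, _resolve_target(work, p, idx))
            for p in rem:
                work.remove_parent(target, _resolve_target(work, p, idx))
    elif op == "merge_classes":
        merged = [
            _resolve_target(work, m, idx) for m in _as_id_list(args.get("merge"))
        ]
        if not merged:
            raise EditScriptError(f"step {idx}: merge_classes requires merge list")
        survivor = work[target]
        for mid in merged:
            if mid == target:
                continue
            if mid in seeds:
                raise EditScriptError(f"step {idx}: refusing to merge seed {mid}")
            loser = work[mid]
            survivor.roles = (*survivor.roles, *loser.roles)
            survivor.alt_ids = (*survivor.alt_ids, *loser.alt_ids, mid)
            survivor.normalize()
            # re-point every reference to the merged id at the survivor
            for other in list(work):
                changed = False
                if mid in other.is_a:
                    other.is_a = tuple(
                        target if p == mid else p for p in other.is_a
                    )
                    changed = True
                if mid in other.roles:
                    other.roles = tuple(
                        target if r == mid else r for r in other.roles
                    )
                    changed = True
                if changed:
                    other.is_a = tuple(p for p in other.is_a if p != other.id)
                    other.roles = tuple(r for r in other.roles if r != other.id)
                    other.normalize()
            work.remove_term(mid, splice=False)
        work.invalidate()
        work.assert_acyclic()
    elif op == "create_other_bucket":
        members = [
            _resolve_target(work, m, idx) for m in _as_id_list(args.get("members"))
        ]
        bucket_name = f"other {work[target].name}".strip()
        siblings = work.children(target)
        existing = [c for c in siblings if work[c].name == bucket_name]
        if existing:
            bucket_id = existing[0]
        else:
            bucket_id = mint_bucket_id(target, str(args.get("prefix", "OTHER")))
            work.add_term(
                Term(
                    id=bucket_id,
                    name=bucket_name,
                    is_a=(target,),
                    subsets=(BUCKET_SUBSET,),
                )
            )
        for mid in members:
            if target in work.parents(mid):
                work.remove_parent(mid, target)
            if bucket_id not in work.parents(mid):
                work.add_parent(mid, bucket_id)
    else:  # pragma: no cover - parse_edit_script already validates op names
        raise EditScriptError(f"step {idx}: unknown op {op!r}")


# ---------------------------------------------------------------------------
# Duplicate-placement checking


def duplicate_placement_report(
    ontology: Ontology,
    level: int = 2,
    exceptions: Iterable[str] = (),
) -> list[dict]:
    """Terms placed under two or more distinct parents at the given level.

    A term sits "at level L under parent P" when P is one of its direct
    parents and P is reachable from a root in exactly L-1 edges. Reviewed
    exceptions (the glycolipid case) are excluded. Rows are sorted by
    (name, id).
    """
    if level < 1:
        raise ValueError("level must be >= 1")
    exceptions = set(exceptions)
    reachable = set(ontology.roots)
    for _ in range(level - 1):
        nxt: set[str] = set()
        for tid in reachable:
            nxt.update(ontology.children(tid))
        reachable = nxt
    rows = []
    for term in ontology:
        if term.obsolete or term.id in exceptions:
            continue
        placements = sorted(
            p for p in term.is_a if p in reachable
        )
        if len(placements) >= 2:
            rows.append(
                {
                    "term_id": term.id,
                    "name": term.name,
                    "level": level,
                    "placements": "; ".join(
                        f"{ontology[p].name} [{p}]" for p in placements
                    ),
                }
            )
    rows.sort(key=lambda r: (r["name"], r["term_id"]))
    return rows


DUPLICATE_COLUMNS = ("term_id", "name", "level", "placements")


# ---------------------------------------------------------------------------
# Orchestration


@dataclass
class SlimResult:
    ontology: Ontology
    prune_log: list[PruneRecord]
    duplicate_rows: list[dict]
    render_text: str


def slim(
    ontology: Ontology,
    seeds: Iterable[str],
    config: Optional[PruneConfig] = None,
    script: Optional[EditScript] = None,
    duplicate_exceptions: Iterable[str] = (),
) -> SlimResult:
    """Run the full pipeline: extract, prune, buckets, script, checks."""
    config = config or PruneConfig()
    seeds = frozenset(seeds)
    work = extract_subset(ontology, seeds)
    work, prune_log = prune_chains(work, seeds, config)
    work = make_other_buckets(work, seeds, config)
    if script is not None and len(script):
        work = apply_edit_script(work, script, seeds=seeds)
    missing = sorted(s for s in seeds if s not in work)
    if missing:  # pragma: no cover - invariant, should never trigger
        raise StructuralError(f"pipeline dropped seed terms: {missing}")
    dup_rows = duplicate_placement_report(
        work, config.level_cap_for_duplicates, duplicate_exceptions
    )
    text = to_indented_text(render_tree(work, seeds))
    return SlimResult(
        ontology=work,
        prune_log=prune_log,
        duplicate_rows=dup_rows,
        render_text=text,
    )
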