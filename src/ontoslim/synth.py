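"""Synthetic ontologies reproducing the pathologies of a real chemical tree.

The generator emulates what makes a raw upstream classification hard to
browse: long single-child chains of grouping classes (a curated entry can
sit 19 levels down), multi-parent placements, a separate role hierarchy
with scattered role assertions, and obsolete/replaced terms. Every
generation is a pure function of its parameters and rng seed, so fixtures
are reproducible byte-for-byte.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .core import Ontology, StructuralError, Term

__all__ = [
    "GeneratorParams",
    "generate_ontology",
    "legacy_chain_fixture",
    "STRUCT_ROOT",
    "ROLE_ROOT",
]

STRUCT_ROOT = "SYN:0000001"
ROLE_ROOT = "SYN:0000002"


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs for synthetic generation.

    Defaults emulate the legacy-tree conditions: a large grouping layer
    with at least one 18-level single-child chain, occasional multi-parent
    placements, a modest role hierarchy with roles asserted on roughly half
    of the curated terms, and a few percent of obsolete terms.
    """

    n_grouping: int = 30
    n_seeds: int = 12
    max_chain_len: int = 18
    p_multiparent: float = 0.15
    n_roles: int = 8
    p_role_assertion: float = 0.5
    p_obsolete: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_multiparent, self.p_role_assertion, self.p_obsolete):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        for n in (self.n_grouping, self.n_seeds, self.max_chain_len, self.n_roles):
            if n < 0:
                raise ValueError("counts must be >= 0")


def generate_ontology(params: GeneratorParams) -> tuple[Ontology, frozenset[str]]:
    """Generate (ontology, seed set), deterministic under ``params.rng_seed``."""
    capacity = 20 * (params.n_grouping + 1)
    if params.n_seeds > capacity:
        raise StructuralError(
            f"n_seeds={params.n_seeds} exceeds capacity {capacity} "
            f"for n_grouping={params.n_grouping}"
        )
    if params.max_chain_len > params.n_grouping and params.max_chain_len > 0 and params.n_grouping > 0:
        raise StructuralError("max_chain_len cannot exceed n_grouping")
    rng = random.Random(params.rng_seed)
    terms: list[Term] = [
        Term(id=STRUCT_ROOT, name="synthetic molecular entity"),
        Term(id=ROLE_ROOT, name="synthetic role"),
    ]
    structural: list[str] = [STRUCT_ROOT]  # attachment points, creation order

    grouping_ids = [f"SYN:1{i:06d}" for i in range(params.n_grouping)]
    chain_end = STRUCT_ROOT
    chain_len = min(params.max_chain_len, params.n_grouping)
    for i in range(chain_len):
        gid = grouping_ids[i]
        terms.append(
            Term(id=gid, name=f"grouping class {i:03d}", is_a=(chain_end,))
        )
        chain_end = gid
        structural.append(gid)
    for i in range(chain_len, params.n_grouping):
        gid = grouping_ids[i]
        parent = rng.choice(structural)
        parents = [parent]
        if rng.random() < params.p_multiparent and len(structural) > 1:
            extra = rng.choice(structural)
            if extra != parent:
                parents.append(extra)
        terms.append(
            Term(id=gid, name=f"grouping class {i:03d}", is_a=tuple(parents))
        )
        structural.append(gid)

    seeds: list[str] = []
    for i in range(params.n_seeds):
        sid = f"SYN:2{i:06d}"
        if i == 0 and chain_len >= 1:
            parents = [chain_end]  # realize the deep-chain pathology
        else:
            parents = [rng.choice(structural)]
        if rng.random() < params.p_multiparent and len(structural) > 1:
            extra = rng.choice(structural)
            if extra not in parents:
                parents.append(extra)
        terms.append(
            Term(
                id=sid,
                name=f"curated compound {i:03d}",
                is_a=tuple(parents),
                is_seed_annotation=True,
            )
        )
        seeds.append(sid)

    role_ids: list[str] = []
    for i in range(params.n_roles):
        rid = f"SYN:3{i:06d}"
        if role_ids and rng.random() < 0.5:
            parent = rng.choice(role_ids)
        else:
            parent = ROLE_ROOT
        terms.append(Term(id=rid, name=f"synthetic role {i:03d}", is_a=(parent,)))
        role_ids.append(rid)

    if role_ids:
        by_id = {t.id: t for t in terms}
        for sid in seeds:
            if rng.random() < params.p_role_assertion:
                by_id[sid].roles = (rng.choice(role_ids),)
                by_id[sid].normalize()
        for gid in grouping_ids:
            if rng.random() < params.p_role_assertion / 2:
                by_id[gid].roles = (rng.choice(role_ids),)
                by_id[gid].normalize()

    live_ids = [t.id for t in terms]
    for i in range(params.n_grouping):
        if rng.random() < params.p_obsolete:
            replacement = rng.choice(live_ids) if rng.random() < 0.5 else None
            terms.append(
                Term(
                    id=f"SYN:4{i:06d}",
                    name=f"retired class {i:03d}",
                    obsolete=True,
                    replaced_by=replacement,
                )
            )

    return Ontology(terms), frozenset(seeds)


def legacy_chain_fixture(
    chain_len: int, n_protected: int
) -> tuple[Ontology, frozenset[str], frozenset[str]]:
    """Canonical regression fixture: root -> chain of grouping classes -> one seed.

    ``n_protected`` chain classes, evenly spaced, are returned as the
    protected set — they model manually retained checkpoint classes, so
    pruning the 18-class chain with 5 checkpoints leaves the seed at depth
    6 instead of collapsing it to depth 1.
    """
    if chain_len < 1:
        raise StructuralError("chain_len must be >= 1")
    if not 0 <= n_protected <= chain_len:
        raise StructuralError("n_protected must be within [0, chain_len]")
    terms = [Term(id=STRUCT_ROOT, name="synthetic molecular entity")]
    prev = STRUCT_ROOT
    chain: list[str] = []
    for i in range(chain_len):
        gid = f"SYN:1{i:06d}"
        terms.append(Term(id=gid, name=f"grouping class {i:03d}", is_a=(prev,)))
        chain.append(gid)
        prev = gid
    seed = "SYN:2000000"
    terms.append(
        Term(id=seed, name="curated compound 000", is_a=(prev,), is_seed_annotation=True)
    )
    step = (chain_len + 1) / (n_protected + 1)
    protected = frozenset(
        chain[min(chain_len - 1, int(round(step * (k + 1))) - 1)]
        for k in range(n_protected)
    )
    return Ontology(terms), frozenset([seed]), protected
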