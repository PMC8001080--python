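"""Browsable tree views of the ontology DAG, with per-branch entry counts.

A multi-parent term appears once under each of its parents, exactly as a
tree browser displays a DAG. Each node carries the number of distinct
curated (seed) entries at or below it, shown at the end of the label the
way the IEDB finder annotates branches. Siblings sort by name, except
"other ..." buckets, which always come last.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .core import Ontology, UnknownTermError

__all__ = ["RenderedNode", "render_tree", "to_indented_text", "to_jsonable", "is_other_name"]


def is_other_name(name: str) -> bool:
    """Whether a term name marks an "other" bucket (sorted last among siblings)."""
    return name.lower().startswith("other ") or name.lower() == "other"


@dataclass
class RenderedNode:
    id: str
    name: str
    entry_count: int
    children: list["RenderedNode"] = field(default_factory=list)


def _seed_counts(ontology: Ontology, seeds: Iterable[str]) -> dict[str, int]:
    """Distinct-seed-descendant count (including self) for every term."""
    counts = {t.id: 0 for t in ontology}
    for seed in sorted(set(seeds)):
        counts[seed] += 1
        for anc in ontology.ancestors(seed):
            counts[anc] += 1
    return counts


def _sibling_key(node: RenderedNode) -> tuple:
    return (is_other_name(node.name), node.name, node.id)


def render_tree(
    ontology: Ontology,
    seeds: Iterable[str],
    roots: Optional[Sequence[str]] = None,
) -> list[RenderedNode]:
    """Expand the DAG below ``roots`` (default: ontology roots) into a forest."""
    if roots is None:
        roots = ontology.roots
    else:
        for r in roots:
            if r not in ontology:
                raise UnknownTermError(r)
    counts = _seed_counts(ontology, seeds)

    def build(term_id: str) -> RenderedNode:
        term = ontology[term_id]
        node = RenderedNode(id=term.id, name=term.name, entry_count=counts[term_id])
        kids = [build(c) for c in ontology.children(term_id)]
        node.children = sorted(kids, key=_sibling_key)
        return node

    forest = [build(r) for r in roots]
    return sorted(forest, key=_sibling_key)


def to_indented_text(forest: Sequence[RenderedNode], indent: str = "  ") -> str:
    """Plain-text outline; entry count at the end of each branch label."""
    lines: list[str] = []

    def emit(node: RenderedNode, level: int) -> None:
        label = node.name or node.id
        lines.append(f"{indent * level}{label} [{node.id}] ({node.entry_count})")
        for child in node.children:
            emit(child, level + 1)

    for node in forest:
        emit(node, 0)
    return "\n".join(lines) + "\n"


def to_jsonable(forest: Sequence[RenderedNode]) -> list[dict]:
    def conv(node: RenderedNode) -> dict:
        return {
            "id": node.id,
            "name": node.name,
            "entry_count": node.entry_count,
            "children": [conv(c) for c in node.children],
        }

    return [conv(n) for n in forest]


def to_json_text(forest: Sequence[RenderedNode]) -> str:
    return json.dumps(to_jsonable(forest), indent=2, sort_keys=False) + "\n"
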