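"""Tree-complexity statistics for before/after comparison of a slimmed view.

The statistics quantify how navigable a hierarchy is for a curator: how
deep the curated ("source") terms sit, and how well parents group them. A
pathological legacy tree has deep single-child chains (median one source
per parent); a well-slimmed tree is shallower and broader.

Depth is path-based on the multi-parent graph; both shortest-path (default
— a browser user reaches a node via its shallowest placement) and
longest-path modes are supported, and comparisons require matching modes.
Medians use the lower-middle element for even counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .core import Ontology, StructuralError

__all__ = [
    "TreeMetrics",
    "TABLE_LABELS",
    "source_depths",
    "parent_child_stats",
    "tree_metrics",
    "compare_metrics",
    "metrics_rows",
    "COMPARE_COLUMNS",
]

TABLE_LABELS = (
    "Average source depth",
    "Median source depth",
    "Maximum source depth",
    "Minimum source depth",
    "Average source count per parent",
    "Median source count per parent",
    "Maximum source count per parent",
    "Parents with one source child",
)

COMPARE_COLUMNS = ("statistic", "old", "new", "delta")


def _median_lower(values: list) -> float:
    # lower-middle convention for even counts
    s = sorted(values)
    if not s:
        raise ValueError("median of empty sequence")
    return s[(len(s) - 1) // 2]


@dataclass(frozen=True)
class TreeMetrics:
    source_depth_avg: float
    source_depth_median: float
    source_depth_max: int
    source_depth_min: int
    children_per_parent_avg: float
    children_per_parent_median: float
    children_per_parent_max: int
    parents_with_one_source_child: int
    n_sources: int
    n_parents: int
    depth_mode: str

    def as_label_map(self) -> dict[str, float]:
        return dict(
            zip(
                TABLE_LABELS,
                (
                    self.source_depth_avg,
                    self.source_depth_median,
                    self.source_depth_max,
                    self.source_depth_min,
                    self.children_per_parent_avg,
                    self.children_per_parent_median,
                    self.children_per_parent_max,
                    self.parents_with_one_source_child,
                ),
            )
        )


def source_depths(
    ontology: Ontology, seeds: Iterable[str], mode: str = "shortest"
) -> list[int]:
    """One depth value per seed (multiset, returned sorted)."""
    return sorted(ontology.depth(s, mode) for s in sorted(set(seeds)))


def parent_child_stats(
    ontology: Ontology, seeds: Iterable[str]
) -> tuple[dict[str, int], int]:
    """Source-bearing-children count per parent, plus the single-source-child tally.

    Parents are all terms that are ancestors of at least one seed and have
    at least one child.
    """
    seeds = set(seeds)
    parent_ids: set[str] = set()
    for seed in seeds:
        parent_ids |= ontology.ancestors(seed)
    counts: dict[str, int] = {}
    for pid in sorted(parent_ids):
        if not ontology.children(pid):
            continue
        counts[pid] = len(ontology.source_bearing_children(pid, seeds))
    single = sum(1 for c in counts.values() if c == 1)
    return counts, single


def tree_metrics(
    ontology: Ontology, seeds: Iterable[str], mode: str = "shortest"
) -> TreeMetrics:
    seeds = set(seeds)
    if not seeds:
        raise StructuralError("tree metrics are undefined for an empty seed set")
    depths = source_depths(ontology, seeds, mode)
    counts, single = parent_child_stats(ontology, seeds)
    per_parent = sorted(counts.values())
    if per_parent:
        cavg = sum(per_parent) / len(per_parent)
        cmed = _median_lower(per_parent)
        cmax = max(per_parent)
    else:  # seeds are all roots: no parents at all
        cavg, cmed, cmax = 0.0, 0, 0
    return TreeMetrics(
        source_depth_avg=sum(depths) / len(depths),
        source_depth_median=_median_lower(depths),
        source_depth_max=max(depths),
        source_depth_min=min(depths),
        children_per_parent_avg=cavg,
        children_per_parent_median=cmed,
        children_per_parent_max=cmax,
        parents_with_one_source_child=single,
        n_sources=len(depths),
        n_parents=len(per_parent),
        depth_mode=mode,
    )


def _fmt(label: str, value: float) -> str:
    # averages render to 1 decimal place; everything else is integral
    if label.startswith("Average"):
        return f"{value:.1f}"
    return str(int(value))


def metrics_rows(metrics: TreeMetrics) -> list[tuple[str, str]]:
    """(label, rendered value) rows for a single tree."""
    return [
        (label, _fmt(label, value))
        for label, value in metrics.as_label_map().items()
    ]


def compare_metrics(
    metrics_old: TreeMetrics, metrics_new: TreeMetrics
) -> list[dict]:
    """Old-vs-new rows, one per statistic, with deltas."""
    if metrics_old.depth_mode != metrics_new.depth_mode:
        raise ValueError(
            f"depth mode mismatch: {metrics_old.depth_mode} vs {metrics_new.depth_mode}"
        )
    old_map = metrics_old.as_label_map()
    new_map = metrics_new.as_label_map()
    rows = []
    for label in TABLE_LABELS:
        delta = new_map[label] - old_map[label]
        rows.append(
            {
                "statistic": label,
                "old": _fmt(label, old_map[label]),
                "new": _fmt(label, new_map[label]),
                "delta": f"{delta:+.1f}" if label.startswith("Average") else f"{int(delta):+d}",
            }
        )
    return rows
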