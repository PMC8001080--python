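"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's own graph traversals: reachability
comes from a numpy boolean-matrix closure (or networkx), depths from
exhaustive path enumeration.
"""

import numpy as np


def closure(ontology):
    """Reflexive-transitive upward reachability via boolean matrix powers.

    Returns (ids, index, R) with R[i, j] true iff ids[j] is ids[i] or an
    ancestor of ids[i].
    """
    ids = list(ontology.ids())
    index = {tid: i for i, tid in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n), dtype=bool)
    for term in ontology:
        for parent in term.is_a:
            A[index[term.id], index[parent]] = True
    R = A | np.eye(n, dtype=bool)
    while True:
        R2 = R | (R @ R)
        if (R2 == R).all():
            return ids, index, R
        R = R2


def ancestors_oracle(ontology, term_id, cl=None):
    ids, index, R = cl or closure(ontology)
    i = index[term_id]
    return frozenset(ids[j] for j in np.flatnonzero(R[i]) if j != i)


def root_path_lengths(ontology, term_id):
    """Lengths of all simple root-to-term paths, by exhaustive DFS."""
    roots = set(ontology.roots)
    lengths = []

    def climb(node, d):
        if node in roots:
            lengths.append(d)
            return
        for parent in ontology[node].is_a:
            climb(parent, d + 1)

    climb(term_id, 0)
    return lengths


def depth_oracle(ontology, term_id, mode):
    lengths = root_path_lengths(ontology, term_id)
    return min(lengths) if mode == "shortest" else max(lengths)


def _median_lower(values):
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def source_bearing_oracle(ontology, parent_id, seeds, cl):
    """Direct children of parent that are seeds or lead down to one."""
    ids, index, R = cl
    seed_rows = [index[s] for s in seeds]
    out = set()
    for child in ontology.children(parent_id):
        j = index[child]
        if child in seeds or any(R[i, j] and i != j for i in seed_rows):
            out.add(child)
    return frozenset(out)


def metrics_oracle(ontology, seeds, mode):
    """All eight tree statistics, recomputed from scratch."""
    cl = closure(ontology)
    ids, index, R = cl
    depths = sorted(depth_oracle(ontology, s, mode) for s in sorted(seeds))
    parent_ids = set()
    for s in seeds:
        parent_ids |= ancestors_oracle(ontology, s, cl)
    counts = {}
    for pid in sorted(parent_ids):
        if not ontology.children(pid):
            continue
        counts[pid] = len(source_bearing_oracle(ontology, pid, seeds, cl))
    per_parent = sorted(counts.values())
    stats = {
        "Average source depth": sum(depths) / len(depths),
        "Median source depth": _median_lower(depths),
        "Maximum source depth": max(depths),
        "Minimum source depth": min(depths),
        "Average source count per parent": (
            sum(per_parent) / len(per_parent) if per_parent else 0.0
        ),
        "Median source count per parent": _median_lower(per_parent) if per_parent else 0,
        "Maximum source count per parent": max(per_parent) if per_parent else 0,
        "Parents with one source child": sum(1 for c in per_parent if c == 1),
    }
    return stats


def seed_ancestry_matrix(ontology, seeds, cl=None):
    """{(a, b): b is strict ancestor of a} over all ordered seed pairs."""
    ids, index, R = cl or closure(ontology)
    seeds = sorted(seeds)
    return {
        (a, b): bool(R[index[a], index[b]]) and a != b
        for a in seeds
        for b in seeds
    }
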