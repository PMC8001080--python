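"""In-memory ontology model and the graph queries every other module builds on.

The model is deliberately small: named classes (terms), ``is_a`` subclass
edges forming a rooted acyclic multi-parent graph, and one existential
relationship ("has role") recorded as a set of role-term targets per term.
This is the fragment of OWL that a curated chemical classification such as
ChEBI actually exercises when it is browsed as a tree.

Conventions used throughout the package:

* Term identifiers are CURIEs (``PREFIX:LOCALID``), compared as exact
  case-sensitive strings.
* All identifier collections inside a :class:`Term` are kept sorted and
  de-duplicated, so that two ontologies with the same content compare equal
  and serialize byte-identically regardless of construction order.
* Obsolete terms stay in the term map (release validation needs to look
  them up) but never contribute to roots, ancestry, depth or metrics.
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

__all__ = [
    "CURIE_RE",
    "OntologyError",
    "InvalidCurieError",
    "UnknownTermError",
    "CycleError",
    "StructuralError",
    "Term",
    "Ontology",
    "validate_curie",
]

#: A CURIE is ``prefix:local`` with exactly one colon and no whitespace.
CURIE_RE = re.compile(r"^[^\s:]+:[^\s:]+$")


class OntologyError(Exception):
    """Base class for all ontology model errors."""


class InvalidCurieError(OntologyError):
    def __init__(self, value: str, line: Optional[int] = None):
        loc = f" (line {line})" if line is not None else ""
        super().__init__(f"not a valid CURIE: {value!r}{loc}")
        self.value = value
        self.line = line


class UnknownTermError(OntologyError):
    def __init__(self, term_id: str):
        super().__init__(f"unknown term: {term_id}")
        self.term_id = term_id


class CycleError(OntologyError):
    """Raised when the is_a graph contains a directed cycle.

    ``cycle`` is a full closed path, first and last element identical.
    """

    def __init__(self, cycle: list[str]):
        super().__init__("is_a cycle: " + " -> ".join(cycle))
        self.cycle = list(cycle)


class StructuralError(OntologyError):
    """An ontology invariant is violated (e.g. a term unreachable from any root)."""


def validate_curie(value: str, line: Optional[int] = None) -> str:
    """Return ``value`` if it is a well-formed CURIE, else raise.

    A CURIE has exactly one ``:`` separating a non-empty prefix from a
    non-empty local id; comparison elsewhere is exact string equality.
    """
    if not isinstance(value, str) or not CURIE_RE.match(value):
        raise InvalidCurieError(str(value), line)
    return value


def _sorted_unique(ids: Iterable[str]) -> tuple[str, ...]:
    return tuple(sorted(set(ids)))


@dataclass
class Term:
    """A single ontology class.

    ``is_a`` holds the structural parents; ``roles`` holds the targets of
    "has role" existential assertions. ``is_seed_annotation`` mirrors an OBO
    subset tag marking membership in the curated seed set. Obsolete terms
    carry no parents or roles; ``replaced_by`` may only be set on obsolete
    terms.
    """

    id: str
    name: str = ""
    is_a: tuple[str, ...] = ()
    roles: tuple[str, ...] = ()
    alt_ids: tuple[str, ...] = ()
    obsolete: bool = False
    replaced_by: Optional[str] = None
    is_seed_annotation: bool = False
    subsets: tuple[str, ...] = ()
    synonyms: tuple[str, ...] = ()  # preserved verbatim, unused semantically

    def __post_init__(self) -> None:
        validate_curie(self.id)
        self.normalize()

    def normalize(self) -> None:
        """Canonicalize collections (sorted, unique) and check local invariants."""
        self.is_a = _sorted_unique(self.is_a)
        self.roles = _sorted_unique(self.roles)
        self.alt_ids = _sorted_unique(self.alt_ids)
        self.subsets = _sorted_unique(self.subsets)
        self.synonyms = tuple(self.synonyms)
        if self.obsolete:
            # Obsolete terms never participate in the browse graph.
            self.is_a = ()
            self.roles = ()
        if self.replaced_by is not None and not self.obsolete:
            raise StructuralError(
                f"{self.id}: replaced_by set on a non-obsolete term"
            )
        overlap = set(self.is_a) & set(self.roles)
        if overlap:
            raise StructuralError(
                f"{self.id}: ids in both is_a and roles: {sorted(overlap)}"
            )

    def copy(self) -> "Term":
        return copy.deepcopy(self)


class Ontology:
    """A rooted acyclic multi-parent class graph.

    The term map is the single source of truth; parent/child indexes are
    derived and rebuilt lazily after mutation. Iteration is always in
    sorted-id order so every downstream serialization is deterministic.
    """

    def __init__(self, terms: Iterable[Term] = (), validate: bool = True):
        self._terms: dict[str, Term] = {}
        for term in terms:
            if term.id in self._terms:
                raise StructuralError(f"duplicate term id: {term.id}")
            self._terms[term.id] = term
        self._children: Optional[dict[str, tuple[str, ...]]] = None
        if validate:
            self.validate()

    # -- container protocol -------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._terms

    def __getitem__(self, term_id: str) -> Term:
        try:
            return self._terms[term_id]
        except KeyError:
            raise UnknownTermError(term_id) from None

    def __iter__(self) -> Iterator[Term]:
        for tid in sorted(self._terms):
            yield self._terms[tid]

    def __len__(self) -> int:
        return len(self._terms)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Ontology):
            return NotImplemented
        return self._terms == other._terms

    def ids(self) -> tuple[str, ...]:
        return tuple(sorted(self._terms))

    def copy(self) -> "Ontology":
        clone = Ontology.__new__(Ontology)
        clone._terms = {tid: t.copy() for tid, t in self._terms.items()}
        clone._children = None
        return clone

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Check referential integrity and acyclicity.

        Dangling ``is_a``/``roles`` references are a structural error: the
        loader is responsible for either resolving or dropping them before an
        Ontology is built.
        """
        for term in self._terms.values():
            for ref in (*term.is_a, *term.roles):
                if ref not in self._terms:
                    raise StructuralError(
                        f"{term.id}: dangling reference to {ref}"
                    )
        self.assert_acyclic()

    def assert_acyclic(self) -> None:
        """Raise :class:`CycleError` with one full cycle path if is_a cycles."""
        WHITE, GREY, BLACK = 0, 1, 2
        color = {tid: WHITE for tid in self._terms}
        for start in sorted(self._terms):
            if color[start] != WHITE:
                continue
            stack: list[tuple[str, Iterator[str]]] = [
                (start, iter(self._terms[start].is_a))
            ]
            color[start] = GREY
            path = [start]
            while stack:
                node, it = stack[-1]
                advanced = False
                for parent in it:
                    if parent not in self._terms:
                        continue
                    if color[parent] == GREY:
                        cycle = path[path.index(parent):] + [parent]
                        raise CycleError(cycle)
                    if color[parent] == WHITE:
                        color[parent] = GREY
                        path.append(parent)
                        stack.append((parent, iter(self._terms[parent].is_a)))
                        advanced = True
                        break
                if not advanced:
                    color[node] = BLACK
                    path.pop()
                    stack.pop()

    # -- derived structure --------------------------------------------------

    @property
    def roots(self) -> tuple[str, ...]:
        """Non-obsolete terms with no structural parents, ordered by (name, id)."""
        roots = [
            t for t in self._terms.values() if not t.obsolete and not t.is_a
        ]
        return tuple(t.id for t in sorted(roots, key=lambda t: (t.name, t.id)))

    def _children_index(self) -> dict[str, tuple[str, ...]]:
        if self._children is None:
            index: dict[str, list[str]] = {tid: [] for tid in self._terms}
            for term in self._terms.values():
                for parent in term.is_a:
                    index[parent].append(term.id)
            key = lambda tid: (self._terms[tid].name, tid)
            self._children = {
                parent: tuple(sorted(kids, key=key))
                for parent, kids in index.items()
            }
        return self._children

    def invalidate(self) -> None:
        """Drop derived indexes after direct term mutation."""
        self._children = None

    # -- queries ------------------------------------------------------------

    def parents(self, term_id: str) -> frozenset[str]:
        return frozenset(self[term_id].is_a)

    def children(self, term_id: str) -> tuple[str, ...]:
        self[term_id]  # raise on unknown id
        return self._children_index()[term_id]

    def ancestors(self, term_id: str) -> frozenset[str]:
        """Transitive closure of parents, excluding the term itself."""
        self[term_id]
        seen: set[str] = set()
        frontier = [term_id]
        while frontier:
            nxt: list[str] = []
            for node in frontier:
                for parent in self._terms[node].is_a:
                    if parent not in seen:
                        seen.add(parent)
                        nxt.append(parent)
            frontier = nxt
        return frozenset(seen)

    def descendants(self, term_id: str) -> frozenset[str]:
        """Transitive closure of children, excluding the term itself."""
        self[term_id]
        index = self._children_index()
        seen: set[str] = set()
        frontier = [term_id]
        while frontier:
            nxt: list[str] = []
            for node in frontier:
                for child in index[node]:
                    if child not in seen:
                        seen.add(child)
                        nxt.append(child)
            frontier = nxt
        return frozenset(seen)

    def source_bearing_children(
        self, term_id: str, seeds: Iterable[str]
    ) -> frozenset[str]:
        """Direct children that are seeds or carry at least one seed descendant."""
        seed_set = set(seeds)
        result = set()
        for child in self.children(term_id):
            if child in seed_set or (self.descendants(child) & seed_set):
                result.add(child)
        return frozenset(result)

    def depth(self, term_id: str, mode: str = "shortest") -> int:
        """Number of is_a edges on the shortest/longest root-to-term path.

        Roots are at depth 0. A term from which no root can be reached by
        climbing parents (possible only when the ontology is malformed, e.g.
        all upward paths dead-end in obsolete parentless terms) raises
        :class:`StructuralError`.
        """
        if mode not in ("shortest", "longest"):
            raise ValueError(f"depth mode must be shortest|longest, got {mode!r}")
        self[term_id]
        root_set = set(self.roots)
        if term_id in root_set:
            return 0
        if mode == "shortest":
            seen = {term_id}
            frontier = [term_id]
            d = 0
            while frontier:
                d += 1
                nxt: list[str] = []
                for node in frontier:
                    for parent in self._terms[node].is_a:
                        if parent in root_set:
                            return d
                        if parent not in seen:
                            seen.add(parent)
                            nxt.append(parent)
                frontier = nxt
            raise StructuralError(f"{term_id}: unreachable from any root")
        # longest: topological DP over the ancestor-induced subgraph
        nodes = set(self.ancestors(term_id)) | {term_id}
        indeg = {n: sum(1 for p in self._terms[n].is_a if p in nodes) for n in nodes}
        down: dict[str, list[str]] = {n: [] for n in nodes}
        for n in nodes:
            for p in self._terms[n].is_a:
                if p in nodes:
                    down[p].append(n)
        order: list[str] = sorted(n for n in nodes if indeg[n] == 0)
        queue = list(order)
        dist: dict[str, int] = {n: 0 for n in queue if n in root_set}
        while queue:
            node = queue.pop(0)
            for child in down[node]:
                indeg[child] -= 1
                if node in dist:
                    cand = dist[node] + 1
                    if cand > dist.get(child, -1):
                        dist[child] = cand
                if indeg[child] == 0:
                    queue.append(child)
        if term_id not in dist:
            raise StructuralError(f"{term_id}: unreachable from any root")
        return dist[term_id]

    def minimal_terms(self, ids: Iterable[str]) -> frozenset[str]:
        """Drop every member that is a strict ancestor of another member.

        What remains are the most specific members: the right attachment
        points when placing a term under its roles.
        """
        members = {tid for tid in ids}
        for tid in members:
            self[tid]
        strict_ancestors: set[str] = set()
        for tid in members:
            strict_ancestors |= self.ancestors(tid) & members
        return frozenset(members - strict_ancestors)

    # -- mutation -----------------------------------------------------------

    def add_term(self, term: Term) -> None:
        if term.id in self._terms:
            raise StructuralError(f"duplicate term id: {term.id}")
        self._terms[term.id] = term
        self.invalidate()

    def remove_term(
        self, term_id: str, splice: bool = True, transfer_roles: bool = False
    ) -> Term:
        """Remove a term; with ``splice`` re-attach its children to all its parents.

        With ``transfer_roles`` the removed term's role assertions move onto
        the spliced children, so role inheritance below the splice point is
        unchanged. References to the removed id in other terms' roles are
        dropped.
        """
        term = self[term_id]
        parents = term.is_a
        for other in self._terms.values():
            if other.id == term_id:
                continue
            if term_id in other.is_a:
                new_parents = [p for p in other.is_a if p != term_id]
                if splice:
                    new_parents.extend(p for p in parents if p != other.id)
                    if transfer_roles and term.roles:
                        other.roles = (
                            *other.roles,
                            *(r for r in term.roles if r != other.id),
                        )
                other.is_a = tuple(new_parents)
                other.normalize()
            if term_id in other.roles:
                other.roles = tuple(r for r in other.roles if r != term_id)
                other.normalize()
        del self._terms[term_id]
        self.invalidate()
        return term

    def set_parents(self, term_id: str, parents: Iterable[str]) -> None:
        term = self[term_id]
        parents = list(parents)
        for p in parents:
            self[p]
        old = term.is_a
        term.is_a = tuple(parents)
        term.normalize()
        self.invalidate()
        try:
            self._check_no_new_cycle(term_id)
        except CycleError:
            term.is_a = old
            self.invalidate()
            raise

    def add_parent(self, term_id: str, parent_id: str) -> None:
        term = self[term_id]
        self[parent_id]
        if term_id == parent_id:
            raise CycleError([term_id, term_id])
        old = term.is_a
        term.is_a = (*term.is_a, parent_id)
        term.normalize()
        self.invalidate()
        try:
            self._check_no_new_cycle(term_id)
        except CycleError:
            term.is_a = old
            self.invalidate()
            raise

    def remove_parent(self, term_id: str, parent_id: str) -> None:
        term = self[term_id]
        if parent_id not in term.is_a:
            raise StructuralError(f"{parent_id} is not a parent of {term_id}")
        term.is_a = tuple(p for p in term.is_a if p != parent_id)
        term.normalize()
        self.invalidate()

    def _check_no_new_cycle(self, term_id: str) -> None:
        """Cheap local check: a cycle through term_id exists iff term_id is its own ancestor."""
        if term_id in self.ancestors(term_id):
            # reconstruct one closed path for the error message
            path = self._path_up(term_id, term_id)
            raise CycleError(path)

    def _path_up(self, start: str, goal: str) -> list[str]:
        """One parent-direction path start -> ... -> goal (both included)."""
        pred: dict[str, str] = {}
        frontier = [start]
        seen: set[str] = set()
        while frontier:
            nxt: list[str] = []
            for node in frontier:
                for parent in self._terms[node].is_a:
                    if parent == goal:
                        chain = [node]
                        while chain[-1] != start:
                            chain.append(pred[chain[-1]])
                        chain.reverse()
                        return chain + [goal]
                    if parent not in seen and parent in self._terms:
                        seen.add(parent)
                        pred[parent] = node
                        nxt.append(parent)
            frontier = nxt
        raise StructuralError(f"no upward path from {start} to {goal}")
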