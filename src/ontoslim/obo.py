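"""OBO 1.4 flat-file dialect: parsing, canonical writing, seed lists, reports.

Only the tags a curated chemical classification needs are interpreted:
``id``, ``name``, ``is_a``, ``relationship: has_role``, ``alt_id``,
``subset``, ``synonym``, ``is_obsolete``, ``replaced_by``. Unknown tags and
non-``[Term]`` stanzas are skipped. The writer emits a canonical form (terms
sorted by id, tags in a fixed order) so ``parse(write(o))`` is the identity
on the model and a second serialization is byte-identical.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional, Sequence

from .core import (
    InvalidCurieError,
    Ontology,
    OntologyError,
    StructuralError,
    Term,
    validate_curie,
)

__all__ = [
    "ParseError",
    "ReportError",
    "DEFAULT_SEED_SUBSET",
    "parse_obo",
    "write_obo",
    "read_seeds",
    "write_report",
    "seeds_from_annotations",
    "resolve_seeds",
]

log = logging.getLogger(__name__)

#: OBO subset tag marking curated seed terms (mirrors Term.is_seed_annotation).
DEFAULT_SEED_SUBSET = "curated_seed"

_TAG_SEP = ": "


class ParseError(OntologyError):
    def __init__(self, message: str, line: Optional[int] = None):
        loc = f" (line {line})" if line is not None else ""
        super().__init__(message + loc)
        self.line = line


class ReportError(OntologyError):
    pass


def _strip_comment(value: str) -> str:
    # OBO trailing comments start at " ! "; names themselves never contain it.
    idx = value.find(" ! ")
    if idx >= 0:
        value = value[:idx]
    elif value.endswith(" !"):
        value = value[:-2]
    return value.strip()


def parse_obo(
    text: str,
    allow_dangling: bool = False,
    seed_subset: str = DEFAULT_SEED_SUBSET,
) -> Ontology:
    """Parse an OBO document into an :class:`Ontology`.

    ``allow_dangling`` controls what happens when an ``is_a`` or ``has_role``
    target does not resolve: error (default) or drop-and-log. Malformed
    stanzas, duplicate ids and cycles raise :class:`ParseError` /
    :class:`~ontoslim.core.CycleError` with a line number where available.
    """
    terms: dict[str, Term] = {}
    stanza: Optional[dict] = None
    stanza_line = 0
    in_term_stanza = False

    def finalize() -> None:
        nonlocal stanza
        if stanza is None:
            return
        if "id" not in stanza:
            raise ParseError("[Term] stanza missing id", stanza_line)
        tid = stanza["id"]
        if tid in terms:
            raise ParseError(f"duplicate term id: {tid}", stanza_line)
        obsolete = stanza.get("obsolete", False)
        is_a = stanza.get("is_a", [])
        roles = stanza.get("roles", [])
        if obsolete and (is_a or roles):
            log.info("%s: dropping is_a/roles of obsolete term", tid)
            is_a, roles = [], []
        terms[tid] = Term(
            id=tid,
            name=stanza.get("name", ""),
            is_a=tuple(is_a),
            roles=tuple(roles),
            alt_ids=tuple(stanza.get("alt_ids", [])),
            obsolete=obsolete,
            replaced_by=stanza.get("replaced_by"),
            is_seed_annotation=stanza.get("seed", False),
            subsets=tuple(stanza.get("subsets", [])),
            synonyms=tuple(stanza.get("synonyms", [])),
        )
        stanza = None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("!"):
            continue
        if line.startswith("["):
            finalize()
            in_term_stanza = line == "[Term]"
            if in_term_stanza:
                stanza = {}
                stanza_line = lineno
            continue
        if not in_term_stanza:
            continue  # header or unknown stanza: skipped
        if stanza is None:  # pragma: no cover - defensive
            continue
        if _TAG_SEP not in line:
            raise ParseError(f"malformed line: {raw!r}", lineno)
        tag, _, value = line.partition(_TAG_SEP)
        tag = tag.strip()
        if tag == "id":
            stanza["id"] = validate_curie(_strip_comment(value), lineno)
        elif tag == "name":
            stanza["name"] = _strip_comment(value)
        elif tag == "is_a":
            stanza.setdefault("is_a", []).append(
                validate_curie(_strip_comment(value), lineno)
            )
        elif tag == "relationship":
            parts = _strip_comment(value).split()
            if len(parts) != 2:
                raise ParseError(f"malformed relationship: {value!r}", lineno)
            rel, target = parts
            if rel == "has_role":
                stanza.setdefault("roles", []).append(
                    validate_curie(target, lineno)
                )
            # other relationship types are outside the model: skipped
        elif tag == "alt_id":
            stanza.setdefault("alt_ids", []).append(
                validate_curie(_strip_comment(value), lineno)
            )
        elif tag == "subset":
            name = _strip_comment(value)
            if name == seed_subset:
                stanza["seed"] = True
            else:
                stanza.setdefault("subsets", []).append(name)
        elif tag == "synonym":
            stanza.setdefault("synonyms", []).append(value.strip())
        elif tag == "is_obsolete":
            stanza["obsolete"] = _strip_comment(value) == "true"
        elif tag == "replaced_by":
            stanza["replaced_by"] = validate_curie(_strip_comment(value), lineno)
        # unknown tags: skipped

    finalize()

    if allow_dangling:
        known = set(terms)
        for term in terms.values():
            dropped = [p for p in term.is_a if p not in known]
            dropped += [r for r in term.roles if r not in known]
            if dropped:
                log.warning("%s: dropping dangling references %s", term.id, dropped)
                term.is_a = tuple(p for p in term.is_a if p in known)
                term.roles = tuple(r for r in term.roles if r in known)
                term.normalize()
    return Ontology(terms.values())


def write_obo(
    ontology: Ontology, seed_subset: str = DEFAULT_SEED_SUBSET
) -> str:
    """Serialize to canonical OBO: terms by id, tags in fixed order."""
    lines = ["format-version: 1.4", ""]
    for term in sorted(ontology, key=lambda t: t.id):
        lines.append("[Term]")
        lines.append(f"id: {term.id}")
        if term.name:
            lines.append(f"name: {term.name}")
        for alt in term.alt_ids:
            lines.append(f"alt_id: {alt}")
        subsets = list(term.subsets)
        if term.is_seed_annotation:
            subsets.append(seed_subset)
        for subset in sorted(subsets):
            lines.append(f"subset: {subset}")
        for syn in term.synonyms:
            lines.append(f"synonym: {syn}")
        for parent in term.is_a:
            lines.append(f"is_a: {parent}")
        for role in term.roles:
            lines.append(f"relationship: has_role {role}")
        if term.obsolete:
            lines.append("is_obsolete: true")
        if term.replaced_by:
            lines.append(f"replaced_by: {term.replaced_by}")
        lines.append("")
    return "\n".join(lines)


def read_seeds(text: str) -> frozenset[str]:
    """Parse a seed list: one CURIE per line, ``#`` comments and blanks allowed."""
    seeds: set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            seeds.add(validate_curie(line, lineno))
        except InvalidCurieError:
            raise ParseError(f"malformed CURIE in seed list: {line!r}", lineno)
    return frozenset(seeds)


def seeds_from_annotations(ontology: Ontology) -> frozenset[str]:
    """Seed ids carried as OBO subset annotations on the ontology itself."""
    return frozenset(
        t.id for t in ontology if t.is_seed_annotation and not t.obsolete
    )


def resolve_seeds(
    ontology: Ontology, file_seeds: Optional[Iterable[str]] = None
) -> frozenset[str]:
    """Determine the effective seed set.

    A seed-list file wins over in-ontology subset annotations; disagreement
    is logged. Unresolvable seeds raise with the full offender list.
    """
    annotated = seeds_from_annotations(ontology)
    if file_seeds is None:
        seeds = annotated
    else:
        seeds = frozenset(file_seeds)
        if annotated and annotated != seeds:
            log.warning(
                "seed file overrides subset annotations (%d only in file, %d only annotated)",
                len(seeds - annotated),
                len(annotated - seeds),
            )
    missing = sorted(s for s in seeds if s not in ontology)
    if missing:
        raise StructuralError(f"unresolvable seed ids: {missing}")
    return seeds


def write_report(
    rows: Iterable[Mapping[str, object] | Sequence[object]],
    columns: Sequence[str],
) -> str:
    """Render rows as a tab-separated report with a header line.

    Rows may be mappings (keyed by column) or sequences (positional); ragged
    rows are an error. Row order is the caller's: every producer in this
    package sorts before writing.
    """
    out = ["\t".join(columns)]
    for i, row in enumerate(rows):
        if isinstance(row, Mapping):
            missing = [c for c in columns if c not in row]
            if missing:
                raise ReportError(f"row {i} missing columns {missing}")
            values = [row[c] for c in columns]
        else:
            values = list(row)
            if len(values) != len(columns):
                raise ReportError(
                    f"row {i} has {len(values)} fields, expected {len(columns)}"
                )
        fields = [str(v).replace("\t", " ").replace("\n", " ") for v in values]
        out.append("\t".join(fields))
    return "\n".join(out) + "\n"
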