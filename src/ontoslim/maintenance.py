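"""Release-over-release maintenance: id validation and naming lint.

``validate_ids`` supports the weekly rebuild gate: every term id used by
the curated data is checked against a fresh upstream release, resolving
retirements through ``replaced_by`` and merges through ``alt_id`` before
declaring anything missing. ``lint_names`` flags capitalization and plural
forms that violate the naming convention (lower case unless mid-sentence
capitalization is expected; singular form); it warns only, never mutates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .core import Ontology

__all__ = [
    "ValidationRow",
    "ValidationReport",
    "validate_ids",
    "LintWarning",
    "lint_names",
    "DEFAULT_CASE_EXCEPTIONS",
    "DEFAULT_PLURAL_WHITELIST",
    "VALIDATION_COLUMNS",
]

VALIDATION_COLUMNS = ("used_id", "status", "replacement")

GATE_FAILING_STATUSES = frozenset({"obsolete_no_replacement", "missing"})


@dataclass(frozen=True)
class ValidationRow:
    used_id: str
    status: str  # valid | replaced | obsolete_no_replacement | merged_via_alt_id | missing
    replacement: Optional[str] = None

    def as_mapping(self) -> dict:
        return {
            "used_id": self.used_id,
            "status": self.status,
            "replacement": self.replacement or "",
        }


@dataclass
class ValidationReport:
    rows: list[ValidationRow]

    @property
    def ok(self) -> bool:
        return not any(r.status in GATE_FAILING_STATUSES for r in self.rows)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for row in self.rows:
            out[row.status] = out.get(row.status, 0) + 1
        return out


def validate_ids(
    used_ids: Iterable[str], new_ontology: Ontology
) -> ValidationReport:
    """Classify every used id against a new release; one row per id.

    Statuses partition the inputs: present & live -> ``valid``; obsolete
    with a replacement -> ``replaced``; obsolete without ->
    ``obsolete_no_replacement``; absent but found in some term's alt_id
    list (an OBO merge) -> ``merged_via_alt_id`` with the host id; else
    ``missing``. Duplicate input ids are reported once, in first-seen order.
    """
    alt_host: dict[str, str] = {}
    for term in new_ontology:  # sorted-id iteration: deterministic host choice
        for alt in term.alt_ids:
            alt_host.setdefault(alt, term.id)

    rows: list[ValidationRow] = []
    seen: set[str] = set()
    for used in used_ids:
        if used in seen:
            continue
        seen.add(used)
        if used in new_ontology:
            term = new_ontology[used]
            if not term.obsolete:
                rows.append(ValidationRow(used, "valid"))
            elif term.replaced_by:
                rows.append(ValidationRow(used, "replaced", term.replaced_by))
            else:
                rows.append(ValidationRow(used, "obsolete_no_replacement"))
        elif used in alt_host:
            rows.append(ValidationRow(used, "merged_via_alt_id", alt_host[used]))
        else:
            rows.append(ValidationRow(used, "missing"))
    return ValidationReport(rows)


# -- naming lint ------------------------------------------------------------

#: First tokens allowed to start with a capital: atom symbols and common
#: abbreviations that would be capitalized mid-sentence.
DEFAULT_CASE_EXCEPTIONS = frozenset(
    {
        "Al", "Ag", "As", "Au", "Ba", "Be", "Br", "Ca", "Cd", "Cl", "Co",
        "Cr", "Cs", "Cu", "Fe", "Gd", "He", "Hg", "Li", "Mg", "Mn", "Mo",
        "Na", "Ni", "Pb", "Pd", "Pt", "Rb", "Se", "Si", "Sn", "Sr", "Ti",
        "Zn", "D-", "L-",
    }
)

#: Final tokens ending in "s" that are not plurals.
DEFAULT_PLURAL_WHITELIST = frozenset(
    {"cis", "trans", "bis", "tris", "gas", "pentakis", "hexakis"}
)


@dataclass(frozen=True)
class LintWarning:
    term_id: str
    name: str
    rule: str  # capitalization | plural
    message: str


def lint_names(
    ontology: Ontology,
    case_exceptions: Optional[frozenset[str]] = None,
    plural_whitelist: Optional[frozenset[str]] = None,
) -> list[LintWarning]:
    """Warnings for names violating the lower-case and singular conventions."""
    case_ok = DEFAULT_CASE_EXCEPTIONS if case_exceptions is None else case_exceptions
    plural_ok = (
        DEFAULT_PLURAL_WHITELIST if plural_whitelist is None else plural_whitelist
    )
    warnings: list[LintWarning] = []
    for term in ontology:
        name = term.name
        if not name:
            continue
        tokens = name.split()
        first = tokens[0]
        if (
            len(name) >= 2
            and name[0].isupper()
            and name[1].islower()
            and first not in case_ok
        ):
            warnings.append(
                LintWarning(
                    term.id,
                    name,
                    "capitalization",
                    f"name starts with a capital letter: {name!r}",
                )
            )
        last = tokens[-1]
        if (
            last.endswith("s")
            and not last.endswith("ss")
            and last.lower() not in plural_ok
        ):
            warnings.append(
                LintWarning(
                    term.id,
                    name,
                    "plural",
                    f"name looks plural: {name!r}",
                )
            )
    warnings.sort(key=lambda w: (w.name, w.term_id, w.rule))
    return warnings
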