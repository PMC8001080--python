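"""Edit scripts: ordered, reviewable manual reorganization steps.

Every manual curation judgement (moving citrulline under "other amino
acids", renaming "ethers", merging sparse branches, ...) is recorded as a
step in a YAML document instead of being hard-coded, so a reorganization can
be re-applied to every new upstream release and reviewed like code.

Schema::

    steps:
      - op: rename            # one of VALID_OPS
        target: CHEBI:25698   # TermId (or minted id for create ops)
        new_name: non-aromatic ether
        rationale: free text (may be empty)

Op-specific arguments are any further keys on the step mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .core import OntologyError

__all__ = ["EditStep", "EditScript", "VALID_OPS", "parse_edit_script", "write_edit_script", "EditScriptError"]

VALID_OPS = frozenset(
    {
        "remove_class",
        "splice_class",
        "move_term",
        "merge_classes",
        "rename",
        "create_class",
        "create_other_bucket",
        "remove_parent",
        "add_parent",
    }
)


class EditScriptError(OntologyError):
    pass


@dataclass
class EditStep:
    op: str
    target: str
    args: dict = field(default_factory=dict)
    rationale: str = ""

    def to_mapping(self) -> dict:
        out: dict = {"op": self.op, "target": self.target}
        out.update(self.args)
        out["rationale"] = self.rationale
        return out


@dataclass
class EditScript:
    steps: list[EditStep] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.steps)

    def __iter__(self):
        return iter(self.steps)


def parse_edit_script(text: str) -> EditScript:
    """Parse a YAML edit script, validating op names and required keys."""
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise EditScriptError(f"edit script is not valid YAML: {exc}") from exc
    if doc is None:
        return EditScript()
    if not isinstance(doc, dict) or "steps" not in doc:
        raise EditScriptError("edit script must be a mapping with a 'steps' list")
    raw_steps = doc["steps"] or []
    if not isinstance(raw_steps, list):
        raise EditScriptError("'steps' must be a list")
    steps: list[EditStep] = []
    for i, raw in enumerate(raw_steps):
        if not isinstance(raw, dict):
            raise EditScriptError(f"step {i}: not a mapping")
        op = raw.get("op")
        if op not in VALID_OPS:
            raise EditScriptError(f"step {i}: unknown edit op {op!r}")
        if "target" not in raw:
            raise EditScriptError(f"step {i}: missing target")
        args = {
            k: v
            for k, v in raw.items()
            if k not in ("op", "target", "rationale")
        }
        steps.append(
            EditStep(
                op=op,
                target=str(raw["target"]),
                args=args,
                rationale=str(raw.get("rationale", "") or ""),
            )
        )
    return EditScript(steps)


def write_edit_script(script: EditScript) -> str:
    doc = {"steps": [step.to_mapping() for step in script.steps]}
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)
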