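# Methods

This note documents the model behind `ontoslim`, the parameters that
matter, the numerical and design choices made where several readings were
defensible, what the synthetic generator does and does not emulate, and the
known limitations.

## The ontology model

The in-memory model is the fragment of OWL that a curated chemical
classification exercises when browsed as a tree: named classes (terms),
`is_a` subclass edges forming a rooted acyclic multi-parent graph, and one
existential relationship ("has role") stored as a set of role-term ids per
term. Obsolete terms stay in the term map — release validation needs to
look them up — but carry no edges and never contribute to roots, ancestry,
depth, or metrics. `replaced_by` is only legal on obsolete terms, and no id
may appear in both `is_a` and `roles` of one term.

Determinism is a design requirement, not an afterthought: the weekly
rebuild use case diffs outputs between runs. All identifier collections are
kept sorted and de-duplicated, iteration is in sorted-id order, sibling
order in renders is `(is-other-bucket, name, id)`, and every report sorts
its rows. Two ontologies with equal content serialize byte-identically.

### Depth in a multi-parent graph

Upstream documentation counts "levels" without fixing what a level means
once a term has several root paths. Both readings are implemented:
`shortest` (default — a browser user reaches a node via its shallowest
placement) and `longest`. Every depth-consuming API takes the mode
explicitly, and comparisons refuse to mix modes.

## The slimming pipeline

`slim` composes five stages in a fixed order; each stage is also usable on
its own.

**Extraction** keeps seeds, their ancestors, roles referenced by any
retained term, and those roles' ancestors, restricting all references to
the retained set. Obsolete terms are never retained; an obsolete seed is an
error, because the pipeline-wide invariant is that *no stage ever removes a
seed*.

**Pruning** repeatedly splices out grouping classes that organize almost
nothing. A splice candidate must: have at least one seed descendant (this
is a structure-tree operation — role-hierarchy terms and seedless branches
are never candidates), not be a seed, a root, or in the `protected` set,
and have at most `max_spliceable_children` source-bearing children
(children that are seeds or lead to one). The default threshold of 1
removes single-lineage chains while keeping genuinely branching groupers;
`count_mode: all_children` switches the count to raw children, since the
upstream procedure is not explicit about which it used. Splicing
re-attaches the children of the removed class to *all* of its parents and
moves the removed class's role assertions onto them. Consequences, all
checked by tests against matrix-closure oracles:

* seed-to-seed ancestry is exactly preserved;
* no seed's shortest depth ever increases;
* no seed loses an inherited role;
* pruning is a fixpoint (a second run removes nothing).

Removal order is deterministic (sorted by name then id, re-evaluated after
every splice), and each removal is logged with the parents and re-attached
children at the time of removal.

The `protected` set models manually retained checkpoint classes: on an
18-class single-child chain, default pruning collapses the seed from depth
19 to depth 1; protecting five evenly spaced checkpoints leaves it at
depth 6.

**Bucket synthesis** targets the "fits none of the named subcategories"
clutter. A parent qualifies when it has at least one named grouping child
(non-seed, with children) and at least `other_bucket_min` (default 3 — a
bucket for one or two stragglers costs more navigation than it saves)
direct children that are seeds or leaves with no grouping-class placement
under the same parent. Those children move into a synthesized
`other {parent}` class. Bucket ids are minted deterministically in a
dedicated namespace (`OTHER:{parent id with ':' replaced}`), an existing
"other ..." sibling is reused rather than collided with, buckets never
nest, and the operation is idempotent. Only parents with seed descendants
qualify, so the role and compound branches never grow buckets.

**Edit scripts** make every manual judgement replayable: ordered YAML steps
(`rename`, `move_term`, `add_parent`/`remove_parent`, `merge_classes`,
`remove_class`/`splice_class`, `create_class`, `create_other_bucket`), each
carrying a free-text rationale. `remove_class` and `splice_class` share
splice semantics (children re-attach to all parents); `merge_classes`
re-points every reference to the merged ids at the survivor and records
them as `alt_id`s, mirroring the upstream merge convention. Steps resolve
targets by id or unique name at application time; a step that would remove
a seed or create a cycle fails with its step index (and the full cycle
path). The shipped `examples/edit_script.yaml` is illustrative; real
curation scripts are expected to live with the deployment's data.

**Duplicate placement** is checked level-wise: a term is flagged when two
or more of its direct parents are reachable from a root in exactly
`level - 1` edges (default level 2, matching the design goal that second-
level nodes appear once). Reviewed exceptions — the glycolipid-style
deliberate dual placement — are passed in and suppressed.

## Role materialization

Role assertions are existential axioms and therefore invisible to a tree
browser. `mirror_roles` builds the browsable counterpart:

* a top term "chemical entity by role" is added as a sibling of the
  designated structural root;
* a role is *in use* when at least one seed holds it, directly or
  inherited; each in-use role gets a compound class whose id is a
  deterministic function of the role id (`CPD:{role id}`) and whose name
  follows the `{role} compound` template unless overridden per role
  (curators sometimes prefer the bare role name);
* compound `is_a` edges mirror the in-use fragment of the role hierarchy:
  each compound points at the compounds of its role's *nearest* in-use
  ancestors, or at the top term when there are none, so gaps of unused
  roles are bridged;
* each seed attaches under the compounds of its **minimal** inherited roles
  only — broader roles are reachable through the mirrored edges, so
  minimal placement avoids double listing.

`inherited_roles` is deliberately an assertion-level union over the term
and its structural ancestors, *without* closing over the role hierarchy:
placement wants minimal roles, and role-hierarchy reachability is delivered
by the mirrored edges instead. Inheritance is computed within the ontology
at hand; roles asserted on ancestors outside an extracted subset do not
count (the extraction preserves exactly the assertions its retained terms
carry).

Compound terms are tagged with a `role_compound` subset annotation, which
is how gap reports and bucket synthesis recognize and skip them, and how a
re-run recognizes existing compounds — mirroring is idempotent.

### The review loop

`role_gap_report` lists seeds with no inherited role, either all of them or
only those whose every structural parent is an "other ..." bucket (the
poorly placed compounds worth reviewing first). Reviewed dispositions come
back as rows: `NR` persists a `no_role` subset annotation (the term is
deliberately role-less — e.g. synthesized only to provoke an immune
response — and leaves all future gap reports), a CURIE asserts an existing
role, and `NEW:name|parent` mints a role under a parent that must lie
inside the designated role branch. New-role ids are deterministic slugs of
the name, so re-applying an assignment file is stable. Conflicting
duplicate rows for one term are an error; identical duplicates are
harmless.

## Metrics

Eight statistics summarize navigability: average/median/maximum/minimum
source depth (one value per seed, in the chosen depth mode) and
average/median/maximum source count per parent plus the count of parents
with exactly one source-bearing child. "Parents" are terms that are
ancestors of at least one seed and have at least one child; the per-parent
count is the source-bearing-children count, consistent with the
single-child-chain pathology these statistics exist to expose (a raw-child
reading is available through the pruning config for sensitivity checks).
Medians use the lower-middle element for even counts — a documented
convention; nothing downstream depends on it. Averages render to one
decimal place in reports and keep full precision in the model. Comparison
tables carry one row per statistic with old, new, and delta.

## The synthetic generator

`generate_ontology` emulates the upstream pathologies under explicit,
seeded randomness (one `random.Random` stream per generation; no global
state): a single structural root plus a role-branch root; a guaranteed
single-child chain of `max_chain_len` grouping classes with a seed at its
end (default 18, putting that seed at depth 19); further grouping classes
attached uniformly at random with an extra parent at probability
`p_multiparent` (attachment only to earlier-created terms, so cycles are
impossible by construction); seeds as leaves or near-leaves; a small role
hierarchy with assertions on seeds at `p_role_assertion` (default 0.5) and
on grouping classes at half that rate, so inheritance paths get exercised;
and obsolete terms, half with `replaced_by`, at `p_obsolete`. Identical
parameters and seed give byte-identical serializations.

What it does **not** emulate: real degree and depth distributions, chemical
plausibility of names, synonym/xref richness, or cross-ontology links.
Passing tests on this corpus therefore demonstrate structural correctness
of the algorithms — ancestry preservation, mirror isomorphism, round-trip
identity — not fidelity of any particular published tree, whose content
depends on external releases and curation data.

Property corpora used by the acceptance suite are sized for exhaustive
oracle comparison: 200 ontologies of at most 60 terms (chains of 8) for
ancestry preservation, 100 for the metrics and mirror suites, all checked
against numpy boolean-matrix closures and path-enumeration oracles written
independently of the library code.

## Serialization

The OBO dialect covers the tags this workflow needs (`id`, `name`, `is_a`,
`relationship: has_role`, `alt_id`, `subset`, `synonym`, `is_obsolete`,
`replaced_by`); unknown tags and stanzas are skipped, other relationship
types are ignored, and dangling references are an error unless
`allow_dangling` drops and logs them. Seed membership travels as a subset
tag (`curated_seed` by default); a seed-list file wins over annotations on
conflict, with a logged warning. The writer emits a canonical form — terms
sorted by id, tags in fixed order — so parse∘write is the identity on the
model and the writer is a serialization fixpoint. Obsolete terms are
normalized to edge-free at parse time, matching what the writer would emit.
OWL ingestion is out of scope; the OBO form is line-oriented and
diff-friendly, which the weekly validation loop relies on.

## Release maintenance

`validate_ids` classifies every used id against a new release: `valid`,
`replaced` (obsolete with `replaced_by`), `merged_via_alt_id` (absent as a
term but listed in some term's `alt_id`s — checked before declaring
anything missing, because upstream merges move retired ids there),
`obsolete_no_replacement`, or `missing`. The last two fail the build gate
(CLI exit code 2). No fuzzy name matching is attempted; ids that resolve
neither directly nor through `replaced_by`/`alt_id` are for a human.

`lint_names` enforces the naming conventions heuristically and only warns:
a name whose first character is uppercase with a lowercase second character
is flagged unless its first token is in the exception lexicon (atom
symbols and common abbreviations; all-caps tokens like "DNP" are exempt by
construction), and a final token ending in "s" is flagged unless it ends in
"ss" or sits in the plural whitelist (`cis`, `trans`, `bis`, ...). Both
lexicons are configurable; the defaults are deliberately small and
documented in `ontoslim.maintenance`.

## Known limitations

* Only `is_a` and `has_role` are modeled; no reasoning beyond transitive
  closure, no `intersection_of`/logical definitions, no OWL parsing.
* Tree expansion of the DAG duplicates shared subtrees per parent; for
  extreme multi-parent fan-in the rendered outline grows accordingly.
* Pruning drops grouping classes — their names disappear from the view even
  when a curator might have kept one as a checkpoint; that judgement is
  exactly what `protected` and edit scripts exist to encode.
* Role inheritance is computed within the ontology provided; slimming
  before mirroring is the supported order (and what `slim` does).
* The plural/case lint is a heuristic with a small default lexicon; it
  trades recall for zero false mutations (it never edits).
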