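# ontoslim

Seed-driven slimming of OBO ontologies into browsable, curator-friendly
views.

Large reference ontologies such as ChEBI classify chemical entities with a
rigor aimed at chemists: a single curated compound can sit below dozens of
ancestors, reached through long chains of single-child grouping classes.
For a database team that curates only a few thousand of those entities —
for example, the non-peptidic epitopes (carbohydrates, lipids, drugs,
haptens) that immunologists search in an epitope database — that depth
makes the tree browser nearly unusable. `ontoslim` turns such an ontology
plus a list of curated term ids ("seeds") into a compact application view,
and maintains that view release over release.

## What it does

Given an OBO file, a seed list, and optional reviewed edit scripts:

1. **Extract** the seed closure: seeds, their `is_a` ancestors, the roles
   those terms carry, and the roles' ancestors.
2. **Prune** uncurated grouping classes with at most one source-bearing
   child (configurable), splicing their children onto *all* of their
   parents so every browse path in the multi-parent DAG survives. A chain
   of 18 single-child grouping classes over one curated compound collapses
   to a single edge — or to explicitly `protected` checkpoint classes.
3. **Bucket** leaf entries that fit none of a parent's named subcategories
   into a synthesized `other {parent}` class (rendered last among its
   siblings), so stragglers do not clutter the branch.
4. **Replay edit scripts**: every manual curation judgement (moves, merges,
   renames, dual placements) is data, not code, and re-applies cleanly to
   each new upstream release.
5. **Materialize roles**: existential `has_role` assertions become a
   browsable "chemical entity by role" branch in which each in-use role
   gets a generated compound class ("hormone" → "hormone compound"), the
   compound subclass edges mirror the in-use fragment of the role
   hierarchy, and each seed hangs under its *minimal* inherited roles only.
6. **Report**: role-gap spreadsheets for curator review (with `NR` /
   existing-role / `NEW:name|parent` dispositions fed back in),
   duplicate-placement checks, tree renders with per-branch entry counts,
   and the eight tree-complexity statistics (source depth and
   sources-per-parent distributions) that quantify the simplification.
7. **Validate releases**: used ids are checked against a new upstream
   release, resolving retirements via `replaced_by` and merges via
   `alt_id`; unresolvable ids fail the build gate (exit code 2).

A deterministic synthetic-ontology generator (`ontoslim.synth`) reproduces
the upstream pathologies — deep single-child chains, multi-parent terms,
partial role coverage, obsolete terms — so the whole pipeline is testable
without downloading anything.

## Worked example

`examples/` ships a small ChEBI-flavored ontology in which
`alpha-D-glucose` sits four grouping classes deep on two redundant
lineages, plus a seed list and a one-step edit script:

```sh
ontoslim slim --obo examples/example.obo --seeds examples/seeds.txt \
    --script examples/edit_script.yaml --out out/
cat out/tree.txt
```

```
chemical entity [EX:0000001] (5)
  molecule [EX:0000012] (5)
    aldohexose [EX:0000022] (2)
      alpha-D-glucose [EX:0000100] (1)
      beta-D-galactose [EX:0000101] (1)
    monosaccharide [EX:0000021] (5)
      aldohexose [EX:0000022] (2)
        alpha-D-glucose [EX:0000100] (1)
        beta-D-galactose [EX:0000101] (1)
      other monosaccharide [OTHER:EX_0000021] (3)
        apiose oddity [EX:0000104] (1)
        ribose oddity [EX:0000102] (1)
        sedoheptulose oddity [EX:0000103] (1)
role [EX:0000200] (0)
  sweetening agent [EX:0000201] (0)
```

The number after each label is the count of distinct curated entries at or
below that node. Six single-child grouping classes were spliced out
(`out/prune_log.tsv` lists each with its parents and re-attached children);
the multi-parent `aldohexose` appears once under each surviving lineage;
the three monosaccharides with no named subcategory landed in a synthesized
`other monosaccharide` bucket, listed last. `out/metrics.tsv` reports the
complexity statistics of the result — here the average source depth drops
from 6.4 to 3.6, the median source count per parent rises from 1 to 2, and
the seven single-source-child parents of the input fall to one (put the two
tables side by side with `ontoslim compare`).

Mirroring roles and listing the curation gaps:

```sh
ontoslim roles mirror --obo out/slimmed.obo --seeds examples/seeds.txt \
    --structural-root EX:0000001 --out out/mirrored.obo
ontoslim roles gaps --obo out/mirrored.obo --seeds examples/seeds.txt \
    --mode other --out out/gaps.tsv
```

adds `chemical entity by role` beside the structural root with
`alpha-D-glucose` under `sweetening agent compound`, and writes a
three-row spreadsheet of seeds that sit only in "other" buckets and have
no inherited role — exactly the terms a curator reviews first.

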