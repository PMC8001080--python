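# Illustrative manual-reorganization script. Each step records one reviewed
# curation judgement; steps apply strictly in order.
steps:
  - op: rename
    target: EX:0000022
    new_name: aldohexose
    rationale: grouping-class names use the bare chemical noun
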