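format-version: 1.4

[Term]
id: EX:0000001
name: chemical entity

[Term]
id: EX:0000010
name: molecular structure descriptor
is_a: EX:0000001

[Term]
id: EX:0000011
name: polyatomic entity
is_a: EX:0000010

[Term]
id: EX:0000012
name: molecule
is_a: EX:0000011

[Term]
id: EX:0000013
name: organooxygen entity
is_a: EX:0000012

[Term]
id: EX:0000014
name: oxygen heterocycle parent
is_a: EX:0000013

[Term]
id: EX:0000015
name: oxane family
is_a: EX:0000014

[Term]
id: EX:0000020
name: carbohydrate
is_a: EX:0000012

[Term]
id: EX:0000021
name: monosaccharide
is_a: EX:0000020

[Term]
id: EX:0000022
name: aldohexose grouping
is_a: EX:0000021
is_a: EX:0000015

[Term]
id: EX:0000100
name: alpha-D-glucose
is_a: EX:0000022
relationship: has_role EX:0000201
subset: curated_seed

[Term]
id: EX:0000101
name: beta-D-galactose
is_a: EX:0000022
subset: curated_seed

[Term]
id: EX:0000102
name: ribose oddity
is_a: EX:0000021
subset: curated_seed

[Term]
id: EX:0000103
name: sedoheptulose oddity
is_a: EX:0000021
subset: curated_seed

[Term]
id: EX:0000104
name: apiose oddity
is_a: EX:0000021
subset: curated_seed

[Term]
id: EX:0000200
name: role

[Term]
id: EX:0000201
name: sweetening agent
is_a: EX:0000200

[Term]
id: EX:0000300
name: ethers
is_a: EX:0000012
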