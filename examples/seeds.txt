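# curated non-peptidic structures
EX:0000100
EX:0000101
EX:0000102
EX:0000103
EX:0000104
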