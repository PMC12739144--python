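id	D0	D1
rs0	0	2
rs1	1	0
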