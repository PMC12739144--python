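cell	donor	state
c0	D0	A
c1	D0	B
c2	D1	A
c3	D1	B
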