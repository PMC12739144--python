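id	chrom	tss
G0	chr1	400000
G1	chr1	90000000
G2	chr2	1500000
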