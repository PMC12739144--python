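id	chrom	pos	ref	alt
rs0	chr1	500000	A	G
rs1	chr2	1000000	C	T
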