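%%MatrixMarket matrix coordinate integer general
3 4 8
1 1 5
1 2 3
1 4 2
2 1 1
2 3 7
2 4 4
3 2 2
3 3 1
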