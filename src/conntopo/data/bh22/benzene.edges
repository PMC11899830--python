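# Benzene
1 2
1 6
2 3
3 4
4 5
5 6
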