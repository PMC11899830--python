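# Naphthalene
1 2
1 6
1 8
2 3
3 4
4 5
5 6
6 9
7 8
7 10
9 10
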