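# Chrysene
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
7 14
8 13
9 10
11 12
11 14
11 16
12 13
14 17
15 16
15 18
17 18
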