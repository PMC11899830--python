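# Benzo[a]pyrene
1 2
1 6
1 8
2 3
2 13
3 4
4 5
5 6
6 9
7 8
7 10
7 16
8 11
9 10
9 18
10 17
11 12
11 15
12 13
14 15
14 16
17 20
18 19
19 20
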