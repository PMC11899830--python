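# Coronene
1 2
1 6
1 8
2 3
2 17
3 4
3 11
4 5
4 14
5 6
5 20
6 9
7 8
7 10
8 15
9 10
9 22
11 12
11 24
12 13
13 14
14 18
15 16
16 17
17 23
18 19
19 20
20 21
21 22
23 24
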