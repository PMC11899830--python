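# Perylene
1 2
1 6
1 10
2 3
2 9
3 4
4 5
5 6
6 12
7 8
7 10
8 9
10 11
11 13
11 19
12 13
12 15
13 14
14 17
14 20
15 16
16 17
18 19
18 20
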