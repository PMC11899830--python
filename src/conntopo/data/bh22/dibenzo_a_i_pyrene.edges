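# Dibenzo(a,i)pyrene
1 2
1 6
1 8
2 3
2 13
3 4
4 5
4 17
5 6
5 20
6 9
7 8
7 10
7 16
8 11
9 10
11 12
11 15
12 13
14 15
14 16
14 22
16 23
17 18
18 19
19 20
21 22
21 24
23 24
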