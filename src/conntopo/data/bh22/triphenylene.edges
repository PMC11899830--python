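# Triphenylene
1 2
1 6
1 8
2 3
2 11
3 4
3 14
4 5
4 15
5 6
5 18
6 9
7 8
7 10
9 10
11 12
12 13
13 14
15 16
16 17
17 18
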