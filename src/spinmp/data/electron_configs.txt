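# Ground-state subshell occupancies per atomic number
# Z 1s 2s 2p 3s 3p 3d 4s 4p
1 1 0 0 0 0 0 0 0
2 2 0 0 0 0 0 0 0
3 2 1 0 0 0 0 0 0
4 2 2 0 0 0 0 0 0
5 2 2 1 0 0 0 0 0
6 2 2 2 0 0 0 0 0
7 2 2 3 0 0 0 0 0
8 2 2 4 0 0 0 0 0
9 2 2 5 0 0 0 0 0
10 2 2 6 0 0 0 0 0
11 2 2 6 1 0 0 0 0
12 2 2 6 2 0 0 0 0
13 2 2 6 2 1 0 0 0
14 2 2 6 2 2 0 0 0
15 2 2 6 2 3 0 0 0
16 2 2 6 2 4 0 0 0
17 2 2 6 2 5 0 0 0
18 2 2 6 2 6 0 0 0
19 2 2 6 2 6 0 1 0
20 2 2 6 2 6 0 2 0
21 2 2 6 2 6 1 2 0
22 2 2 6 2 6 2 2 0
23 2 2 6 2 6 3 2 0
24 2 2 6 2 6 5 1 0
25 2 2 6 2 6 5 2 0
26 2 2 6 2 6 6 2 0
27 2 2 6 2 6 7 2 0
28 2 2 6 2 6 8 2 0
29 2 2 6 2 6 10 1 0
30 2 2 6 2 6 10 2 0
31 2 2 6 2 6 10 2 1
32 2 2 6 2 6 10 2 2
33 2 2 6 2 6 10 2 3
34 2 2 6 2 6 10 2 4
35 2 2 6 2 6 10 2 5
36 2 2 6 2 6 10 2 6
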