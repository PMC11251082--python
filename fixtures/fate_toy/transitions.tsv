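from	to	prob
0	1	0.6
0	2	0.4
1	3	0.5
1	4	0.3
1	2	0.2
3	5	0.7
3	6	0.3
4	6	0.6
4	7	0.4
5	8	1.0
6	8	0.5
6	9	0.5
8	12	0.8
8	10	0.2
2	7	0.6
2	9	0.4
7	9	0.3
7	11	0.7
9	10	0.5
9	11	0.5
10	13	0.6
10	14	0.4
11	14	0.9
11	10	0.1
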