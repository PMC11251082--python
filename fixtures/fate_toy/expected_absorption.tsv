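node	X	Y	se_X	se_Y
0	0.441500	0.558500	0.001570	0.001570
1	0.586280	0.413720	0.001557	0.001557
2	0.215880	0.784120	0.001301	0.001301
3	0.829410	0.170590	0.001189	0.001189
4	0.429040	0.570960	0.001565	0.001565
5	0.920670	0.079330	0.000855	0.000855
6	0.624280	0.375720	0.001532	0.001532
7	0.140600	0.859400	0.001099	0.001099
8	0.920370	0.079630	0.000856	0.000856
9	0.331070	0.668930	0.001488	0.001488
10	0.599720	0.400280	0.001549	0.001549
11	0.058530	0.941470	0.000742	0.000742
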