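cell	g1	g2	g3
c0	1.0	0.0	2.0
c1	2.0	1.0	1.0
c2	0.0	3.0	1.5
c3	4.0	0.5	0.0
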