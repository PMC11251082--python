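cell	x	y
c0	0.0	0.0
c1	1.0	0.0
c2	0.0	1.2
c3	2.2	0.4
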