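cell	GeneA	mt-Sim1
c0	95	5
c1	95	5
c2	95	5
c3	95	5
c4	95	5
c5	95	5
c6	75	25
c7	75	25
c8	75	25
c9	75	25
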