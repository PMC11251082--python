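cell	g1	g2	g3
c0	1.75108732951	0.525826042386	1.34557559391
c1	1.5867766334	1.08038103167	1.2322207226
c2	1.7068550615	1.41391862829	1.04287703825
c3	2.00521078943	0.926172446798	1.04741417641
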