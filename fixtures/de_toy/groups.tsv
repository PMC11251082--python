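group	value
a	1.0
a	2.0
a	3.0
b	10.0
b	11.0
b	12.0
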