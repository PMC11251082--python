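fate	node
X	12
X	13
Y	14
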