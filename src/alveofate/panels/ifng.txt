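Ifngr1
Ly6a
Irf7
Cxcl16
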