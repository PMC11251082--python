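Cldn4
Krt8
Nr4a3
Ifngr1
Ndrg1
Sox9
Hmga2
Itga2
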