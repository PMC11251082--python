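Sox9
Etv5
Nkx2-1
Hmga2
Nr4a3
Irf7
Tead1
Foxa2
Gata6
Nfe2l3
Cebpa
Klf5
Sox2
Id2
Tfcp2l1
Elf3
Grhl2
Ehf
Atf3
Junb
Fosb
Egr1
Nfkb1
Stat1
Stat3
Hes1
Hey1
Myc
Trp63
Yap1
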