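receptor	ligand
Ocln	Ocln
Itga3	Lamb3
Adipor1	Adipoq
Plxnb2	Sema4c
Cldn4	Cldn4
St14	Spint1
Itgb1	Fn1
Lsr	Angptl3
Egfr	Egf
Met	Hgf
Fgfr2	Fgf7
Fgfr1	Fgf2
Notch1	Dll1
Notch2	Jag1
Itgb4	Lamb3
Itga6	Lama3
Itgav	Vtn
Itga5	Fn1
Itgb5	Vtn
Itgb6	Tgfb1
Cd44	Hmmr
Axl	Gas6
Ephb2	Efnb1
Epha2	Efna1
Ldlr	Apob
Insr	Ins1
Igf1r	Igf1
Il6ra	Il6
Tnfrsf1a	Tnf
Cxcr4	Cxcl12
Ackr3	Cxcl12
Plaur	Plau
F2r	F2
Gpc1	Fgf2
Sdc1	Fn1
Sdc4	Fn1
Lrp1	Serpine1
Nrp1	Vegfa
Nrp2	Sema3f
Robo1	Slit2
Unc5b	Ntn1
Ptprf	Ptprf
Ptprk	Ptprk
Ddr1	Col1a1
Tyro3	Gas6
Mertk	Gas6
Flt1	Vegfa
Kdr	Vegfa
Tek	Angpt1
Pdgfra	Pdgfa
Pdgfrb	Pdgfb
Tgfbr1	Tgfb1
Tgfbr2	Tgfb1
Bmpr1a	Bmp4
Bmpr2	Bmp4
Acvr1	Inhba
Lifr	Lif
Osmr	Osm
Il1r1	Il1b
Fas	Faslg
Edar	Eda
Celsr1	Celsr1
Fzd1	Wnt3a
Fzd7	Wnt5a
Lgr5	Rspo1
Ryk	Wnt5a
Ror1	Wnt5a
Musk	Agrn
Ntrk2	Bdnf
Sort1	Ngf
Cd74	Mif
Csf1r	Csf1
Kit	Kitl
Flt3	Flt3l
Ret	Gdnf
Erbb2	Nrg1
Erbb3	Nrg1
Gfra1	Gdnf
Cdh1	Cdh1
Jag2	Notch3
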