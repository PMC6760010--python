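# Genes annotated to "mitotic cell cycle" (GO:0000278); synthetic desk-scale
# fixture list assembled from canonical mammalian mitotic genes.
Mki67
Top2a
Ccnb1
Ccnb2
Ccna2
Cdk1
Cdc20
Plk1
Aurka
Aurkb
Bub1
Bub1b
Birc5
Cenpa
Cenpe
Cenpf
Kif11
Kif23
Kif2c
Kif20a
Knl1
Ndc80
Nusap1
Prc1
Racgap1
Spc25
Tpx2
Ube2c
Anln
Aspm
Ccnf
Cdca3
Cdca8
Ckap2
Ect2
Foxm1
Hmmr
Mad2l1
Pbk
Sgo1
Cdc25a
Cdc25b
Cdc25c
Ccne1
Ccne2
Cdk2
Cdk4
Ccnd1
Mcm2
Mcm3
Mcm5
Pcna
Rrm2
Tyms
Wee1
Chek1
Chek2
Espl1
Incenp
Kif4a
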