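# Curated seed list of canonical mitotic cell-cycle marker genes.
Mki67
Top2a
Ccnb1
Ccnb2
Ccna2
Cdk1
Cdc20
Plk1
Aurka
Bub1
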