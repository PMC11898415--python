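# Signed circular gene orders, one taxon per line: "taxon: g1 -g2 g3 ..."
# A leading minus marks light-strand (R) orientation.
pancrustacean_ground: cox1 trnL2 cox2 trnK trnD atp8 atp6 cox3 trnG nad3 trnA trnR trnN trnS1 trnE -trnF -nad5 -trnH -nad4 -nad4L trnT -trnP nad6 cytb trnS2 -nad1 -trnL1 -rrnL -trnV -rrnS CR trnI -trnQ trnM nad2 trnW -trnC -trnY
G_albolineatus: cox1 trnL2 cox2 trnK trnD atp8 atp6 cox3 trnG nad3 trnA trnR trnN trnS1 trnE -trnH -trnF -nad5 -nad4 -nad4L trnT -trnP nad6 cytb trnS2 -nad1 -trnL1 -rrnL -trnV -rrnS CR trnI -trnQ trnM nad2 trnW -trnC -trnY
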