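# fixture species lexicon: miRBase organism code <TAB> synonym
hsa	human
hsa	humans
hsa	Homo sapiens
mmu	mouse
mmu	mice
mmu	murine
rno	rat
rno	rats
cel	Caenorhabditis elegans
cel	C. elegans
dre	zebrafish
gga	chicken
ssc	pig
dme	Drosophila melanogaster
bta	bovine
ath	Arabidopsis thaliana
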