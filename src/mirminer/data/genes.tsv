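# fixture gene/protein lexicon: concept id <TAB> synonym
# G013 carries a miRNA-shaped gene symbol (MIR16, membrane interacting
# protein of RGS16) to exercise the miRNA/gene synonym collision filter.
G001	TP53
G001	tumor protein p53
G002	BACE1
G002	beta-secretase 1
G003	caveolin-1
G003	CAV1
G004	SMN
G004	survival motor neuron
G005	trypsin
G006	PTEN
G007	BCL2
G008	VEGFA
G008	vascular endothelial growth factor A
G009	KRAS
G010	EGFR
G010	epidermal growth factor receptor
G011	RGS16
G012	high-mobility group A2
G012	HMGA2
G013	MIR16
G013	membrane interacting protein of RGS16
G014	STAT3
G015	MYC
G016	CDKN1A
G016	p21
G017	NFKB1
G018	SIRT1
G019	DICER1
G020	AGO2
G020	argonaute 2
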