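# canonical_name	organism_code	accession	internal_id
# minimal registry mapping table; drop in a full miRBase aliases export
# to extend coverage.  An empty accession marks a vocabulary entry with
# no registry identifier.
lin-4	cel	MI0000002	MIR0000007
mir-1	hsa	MIMAT0000416	MIR0000005
mir-171		 	MIR0000008
mir-21	hsa	MI0000077	MIR0000010
mir-16	hsa	MI0000070	MIR0000011
let-7a-1	hsa	MI0000060	MIR0000012
mir-155	hsa	MI0000681	MIR0000013
mir-101	hsa	MI0000103	MIR0000014
mir-124	mmu	MI0000150	MIR0000015
mir-181a	hsa	MI0000269	MIR0000016
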