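# fixture disease lexicon: concept id <TAB> synonym
D001	glioblastoma
D001	glioblastoma multiforme
D002	Parkinson's disease
D002	Parkinson disease
D003	Alzheimer's disease
D003	Alzheimer disease
D004	chronic lymphocytic leukemia
D004	CLL
D005	breast cancer
D005	mammary carcinoma
D006	lung cancer
D007	hepatocellular carcinoma
D007	HCC
D008	colorectal cancer
D009	epilepsy
D010	diabetes mellitus
D010	diabetes
D011	chronic inflammation
D012	cardiac hypertrophy
D013	gastric cancer
D014	melanoma
D015	ovarian cancer
D016	prostate cancer
D017	multiple sclerosis
D018	schizophrenia
D019	osteosarcoma
D020	pancreatic cancer
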