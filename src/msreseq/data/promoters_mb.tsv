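tss	logfc	fdr	gene	class
chr16:51277965	-0.85	3.82e-4	AC137527.2	Pseudogene
chr13:115039303	0.20	1.97e-3	MIR4502	miRNA
chr17:34397734	0.39	4.41e-2	CCL18	Protein coding
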