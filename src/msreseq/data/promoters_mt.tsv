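tss	logfc	fdr	gene	class
chr17:73070401	0.59	9.50e-6	AC111186.1	Pseudogene
chr17:75148756	0.36	4.01e-4	RNU4-47P	snRNA
chr19:48673949	0.60	8.84e-4	ZSWIM9	Protein coding
chr11:46134769	0.55	1.51e-3	AC024475.1	miRNA
chr4:111866955	0.30	1.81e-3	LYPLA1P2	Pseudogene
chr12:7072409	0.25	6.45e-3	U47924.27	lincRNA
chr1:242187356	-0.14	6.93e-3	RNU6-1139P	snRNA
chr12:7072408	0.25	7.37e-3	EMG1	Protein coding
chr11:93971316	1.04	1.67e-2	RP11-680H20.2	lincRNA
chr2:47454056	-0.67	4.96e-2	AC106869.2	lincRNA
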