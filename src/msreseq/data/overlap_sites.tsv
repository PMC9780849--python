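position	mb_logfc	mb_fdr	mt_logfc	mt_fdr	gene
chr2.0003882321	0.88	2.29e-2	0.90	2.40e-2
chr2.0029850455	1.24	6.74e-4	1.32	1.11e-5	ALK
chr2.0033057636	-0.84	3.40e-3	-0.85	1.94e-2	LINC00486
chr2.0035092870	-1.09	1.00e-2	-1.19	8.26e-5	AC012593.1
chr2.0056193463	1.32	1.79e-3	1.55	1.22e-6	RP11-481J13.1, AC011306.2
chr2.0223166989	0.87	4.07e-2	0.90	4.80e-2	CCDC140
chr2.0235215325	-1.05	6.08e-4	-1.08	6.49e-4
chr3.0053784559	0.91	1.58e-2	1.14	8.96e-4	CACNA1D
chr3.0060919598	-0.85	1.89e-3	-0.86	3.09e-2	FHIT
chr3.0119863345	1.28	2.04e-3	1.48	1.19e-5	GPR156
chr3.0119990864	-1.14	2.05e-3	-1.01	4.01e-2	GPR156
chr3.0127606140	-1.40	1.26e-4	-1.12	6.36e-3
chr3.0182124231	-1.14	3.82e-2	-1.15	5.10e-3
chr3.0189791239	-1.34	1.56e-2	-1.13	5.00e-2	LEPREL1
chr3.0196595774	-1.37	3.54e-2	-1.33	1.44e-2	SENP5
chr4.0101719592	-1.04	4.74e-5	-1.15	1.77e-7	EMCN
chr5.0011534641	0.90	2.48e-2	1.05	7.82e-3	CTNND2
chr5.0039219698	1.22	3.91e-2	1.37	2.24e-2	FYB
chr5.0164483805	-0.92	2.51e-2	-1.11	1.05e-3	CTC-340A15.2
chr5.0166472226	-1.03	1.03e-2	-1.16	4.86e-4
chr6.0008948266	1.16	2.27e-2	1.24	2.52e-3
chr6.0016145414	-1.17	2.94e-4	-1.24	9.54e-5	MYLIP
chr6.0019413218	0.81	2.95e-3	0.86	1.70e-2
chr6.0031008851	0.96	2.29e-2	1.01	1.56e-2	RASSF3
chr6.0154640863	1.37	9.68e-3	1.34	3.64e-3	IPCEF1
chr6.0161063597	-2.29	3.71e-3	-1.62	2.31e-2	LPA
chr7.0016768868	-0.75	1.18e-2	-1.03	1.03e-5
chr7.0044621160	0.91	1.71e-2	0.97	4.26e-2	TMED4
chr7.0147581299	-0.68	3.30e-2	-0.83	3.24e-2	CNTNAP2
chr11.0123045794	-1.36	1.13e-3	-1.54	2.08e-6	CLMP
chr11.0129565594	1.28	1.59e-2	1.68	1.23e-4
chr12.0003241735	1.19	4.26e-3	1.04	3.25e-2	TSPAN9
chr12.0026672531	1.00	4.67e-2	1.28	1.68e-2	ITPR2
chr12.0048360477	-1.69	3.13e-4	-1.10	4.25e-2	TMEM106C
chr12.0054366343	0.87	4.94e-2	1.07	3.53e-2	HOTAIR
chr12.0055783991	1.19	4.36e-2	1.29	2.11e-2
chr12.0083436417	1.62	4.94e-3	2.14	6.72e-5	TMTC2
chr12.0114887843	1.42	1.84e-4	0.62	4.91e-2
chr12.0116068191	-1.32	1.42e-2	-1.58	5.07e-6	RP11-1028N23.4
chr12.0128167651	1.13	3.28e-2	1.57	8.87e-14
chr12.0131689822	1.29	2.19e-2	1.74	5.09e-5	RP11-638F5.1
chr13.0021286449	-1.10	4.87e-2	-1.33	2.22e-2	IL17D
chr13.0027424109	1.51	1.23e-2	1.56	5.47e-4
chr13.0033220266	-1.24	5.87e-3	-1.31	2.18e-3	PDS5B
chr13.0047191668	-1.30	6.51e-3	-1.34	6.36e-3	LRCH1
chr13.0093896533	1.50	2.96e-2	2.41	2.86e-5	GPC6
chr13.0099687193	1.01	3.54e-2	1.06	4.85e-2	DOCK9
chr13.0107176083	-1.69	7.74e-3	-1.68	1.29e-2	EFNB2
chr13.0109856377	-1.48	4.00e-2	-1.52	6.19e-3	MYO16
chr14.0021177142	-1.22	3.13e-4	-1.24	7.38e-5
chr14.0021316565	-1.29	2.23e-2	-1.56	2.05e-4
chr14.0025947530	0.91	1.48e-2	1.05	7.13e-3
chr14.0080449863	-1.84	5.11e-5	-1.74	2.05e-4
chr14.0085404000	-1.38	4.50e-3	-1.38	3.07e-3
chr14.0104190006	-1.48	3.71e-3	-1.75	2.66e-4	ZFYVE21
chr15.0046178808	-0.97	1.71e-2	-0.70	4.78e-2	RP11-718O11.1
chr15.0069824154	1.42	1.25e-4	1.55	4.82e-6	RP11-279F6.1
chr15.0092982723	1.45	3.91e-5	1.73	9.39e-9	ST8SIA2
chr16.0004815786	-0.89	8.94e-4	-0.92	9.24e-3	ZNF500
chr16.0077912976	-1.23	8.49e-3	-1.28	2.22e-3	VAT1L
chr16.0079468883	1.11	4.82e-3	1.28	3.78e-5
chr17.0018941025	-1.85	1.91e-3	-1.96	2.09e-4	GRAP
chr17.0019045779	-1.55	7.74e-3	-1.56	8.05e-4	GRAPL, CTC-457L16.2
chr17.0028803808	-1.20	1.47e-2	-1.24	4.72e-3
chr17.0070499160	1.04	1.42e-4	1.06	1.48e-3	LINC00511
chr17.0074566299	0.87	3.28e-2	1.14	3.76e-4	ST6GALNAC2, RP11-666A8.9
chr18.0043923940	-1.66	5.63e-6	-1.73	7.53e-7	RNF165
chr18.0045011716	1.10	2.73e-2	1.41	4.57e-5	CTD-2130O13.1
chr18.0047177650	-1.15	3.29e-4	-0.64	8.52e-3
chr18.0047230566	-1.39	1.98e-2	-1.30	3.48e-3
chr18.0072250823	1.12	7.11e-3	1.05	2.58e-2	CNDP1
chr19.0002867898	1.36	5.19e-9	1.12	1.72e-2	ZNF556
chr19.0041126191	-0.80	1.99e-2	-0.92	4.84e-3	LTBP4
chr20.0031210733	1.20	2.29e-2	1.36	2.68e-2
chr20.0052825772	-1.35	1.91e-3	-1.31	3.11e-3	PFDN4
chr20.0055369320	-1.24	9.46e-4	-1.68	1.37e-4
chr20.0060501154	2.02	6.08e-4	1.87	9.34e-4	CDH4
chr21.0030689317	-0.78	4.49e-3	-0.86	1.16e-3	BACH1
chr22.0050332646	-1.23	5.83e-3	-1.35	1.32e-3
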