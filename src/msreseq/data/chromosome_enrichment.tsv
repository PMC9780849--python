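chrom	mb_sig	mb_p	mt_sig	mt_p	muscle_sig	muscle_p	blood_sig	blood_p
chr1	0	1.000	1	1.000	1	1.000	10	1.000
chr2	26	0.997	103	1.000	84	0.361	312	1.000
chr3	45	4.81e-3	112	0.146	77	9.94e-3	650	2.20e-16
chr4	3	1.000	9	1.000	7	1.000	21	1.000
chr5	14	0.998	82	0.863	64	0.082	222	1.000
chr6	29	0.348	98	0.209	109	1.22e-12	544	2.20e-16
chr7	8	1.000	23	1.000	23	1.000	136	1.000
chr8	9	1.000	26	1.000	28	0.999	169	1.000
chr9	18	0.921	54	1.000	22	1.000	208	1.000
chr10	13	0.999	35	1.000	4	1.000	76	1.000
chr11	33	0.103	101	0.092	58	0.196	618	2.20e-16
chr12	76	2.20e-16	204	2.20e-16	67	7.43e-3	519	2.20e-16
chr13	21	3.73e-2	104	7.37e-14	61	9.60e-9	344	2.20e-16
chr14	41	3.31e-7	137	2.20e-16	68	6.01e-8	448	2.20e-16
chr15	31	1.63e-3	130	2.20e-16	72	6.96e-9	298	3.44e-9
chr16	20	0.835	93	0.111	68	3.04e-3	369	1.37e-5
chr17	26	0.564	86	0.659	56	0.329	300	0.912
chr18	35	4.65e-8	107	2.20e-16	47	1.42e-5	341	2.20e-16
chr19	9	1.000	47	1.000	25	1.000	170	1.000
chr20	47	4.59e-11	153	2.20e-16	64	4.93e-8	484	2.20e-16
chr21	2	0.995	6	1.000	2	1.000	9	1.000
chr22	19	0.101	63	1.09e-2	31	0.257	293	2.20e-16
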