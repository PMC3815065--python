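haplotype	CEU	TSI	GIH	CHB	CHD	JPT	MKK	LWK	YRI	ASW	MEX
C1	0	0	0	0	0	0	7	4	13	1	0
C2	0	0	1	1	0	0	38	26	38	21	1
C2/C3	0	1	0	0	0	0	0	0	0	0	0
C3	0	0	0	14	14	5	3	0	0	0	9
C4	0	0	0	0	0	0	6	14	7	3	0
C5	0	0	0	1	0	1	13	14	50	19	0
C6	0	0	1	34	21	35	52	33	42	20	0
C6/C7	0	0	0	0	0	0	0	0	0	0	7
C7	0	0	2	40	39	36	1	2	3	1	0
C8	0	0	0	0	1	0	0	1	5	3	0
C9	0	0	3	36	44	51	65	63	61	27	15
C10	0	0	1	34	41	37	0	1	0	0	9
C11	109	173	167	3	3	1	92	9	3	22	60
other-d	6	2	1	2	1	1	2	3	0	0	2
other-a	0	0	0	3	6	5	7	10	8	9	1
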