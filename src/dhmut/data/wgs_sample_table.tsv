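sample_id	genotype	tissue	ems_dose	clean_gb	mapped_gb	n_mut_genome	ratio_genome	n_mut_gene	ratio_gene
HTX-2.8_1	HTX	seed	2800	42.94	3.58	15728	4.40	323	2.61
HTX-2.8_2	HTX	seed	2800	46.47	3.60	13936	3.87	314	2.51
HTX-2.8_3	HTX	seed	2800	48.49	3.61	13355	3.70	319	2.55
HTX-4_1	HTX	seed	4000	45.40	3.60	25991	7.23	781	6.26
HTX-4_2	HTX	seed	4000	48.42	3.64	13769	3.79	312	2.46
HTX-4_3	HTX	seed	4000	49.00	3.62	9100	2.51	230	1.82
HTX-0_1	HTX	microspore	0	38.88	3.56	3987	1.12	94	0.76
HTX-0_2	HTX	microspore	0	32.41	3.51	4269	1.22	85	0.71
HTX-0_3	HTX	microspore	0	32.40	3.47	4636	1.34	90	0.75
HTX-0.3_1	HTX	microspore	300	25.97	3.41	5359	1.57	164	1.42
HTX-0.3_2	HTX	microspore	300	27.64	3.42	5894	1.72	143	1.23
HTX-0.3_3	HTX	microspore	300	31.14	3.49	4967	1.42	107	0.90
Hua-0_1	Hua30	microspore	0	47.58	3.57	6641	1.86	147	1.19
Hua-0_2	Hua30	microspore	0	44.75	3.57	6228	1.75	132	1.07
Hua-0_3	Hua30	microspore	0	36.70	3.50	6690	1.91	174	1.46
Hua-0.3_1	Hua30	microspore	300	30.75	3.52	8186	2.32	227	1.89
Hua-0.3_2	Hua30	microspore	300	27.02	3.48	7129	2.05	191	1.61
Hua-0.3_3	Hua30	microspore	300	25.15	3.45	7555	2.19	180	1.56
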