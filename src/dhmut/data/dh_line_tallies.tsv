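genotype	ems_dose	n_dh_lines	n_harvested
HTX	0	45	34
HTX	50	32	22
HTX	100	27	12
HTX	200	36	19
HTX	300	24	12
Hua30	0	94	55
Hua30	50	481	258
Hua30	100	605	434
Hua30	200	787	688
Hua30	300	662	438
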