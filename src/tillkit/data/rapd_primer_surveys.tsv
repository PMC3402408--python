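primer	sequence	primer_length	bands_wt	mutant_bands	m2_screened	reported_kb
A-09	GGGTAACGCC	10	6	1	300	36
A-10	GTGATCGCAG	10	8	3	300	16
UBC3	CCTGGGCTTA	10	7	4	300	10
R1	TCGTGGCTGACTTCACTG	18	8	1	300	86
E4	GAATTCCAGCCTGCA	15	7	2	300	31
IT31	GAAGCCGCAGGTAAG	15	6	2	300	27
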