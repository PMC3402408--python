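category	mutants_observed	population	reported_pct
dwarf and semi-dwarf	35	2610	1.34
spike morphology	16	2610	0.61
tiny plants	8	2610	0.31
albinism	7	2610	0.27
late heading	7	2610	0.27
lower fertility	5	2610	0.19
few tillers	4	2610	0.15
seedling lethal	4	2610	0.15
erect leaf	3	2610	0.11
wide leaf	3	2610	0.11
seed size	3	2610	0.11
deep green leaf	2	2610	0.08
disease sensitive	2	2610	0.08
early senescence	2	2610	0.08
single tiller	2	2610	0.08
narrow leaf	1	2610	0.04
yellow green leaf	1	2610	0.04
wax leaf	1	2610	0.04
multiple tillers	1	2610	0.04
coleoptiles shape	1	2610	0.04
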