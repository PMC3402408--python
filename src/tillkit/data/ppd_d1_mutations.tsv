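individual	nucleotide_change	amino_acid_change	pssm	sift	zygosity	type
P401-2	C1687T	S242S	.	.	Het	.
P346-1	C1793T	Intron	.	.	Het	.
P20-1	C1856T	Intron	.	.	Het	repeat
P20-2	C1856T	Intron	.	.	Hom	repeat
P302-1	G1895A	L276L	.	.	Hom	.
P401-1	G2309A	Intron	.	.	Het	.
P144-1	G2337A	Intron	.	.	Het	.
P283-1	C2353T	Intron	.	.	Hom	.
P127-1	G2401A	G418S	.	0.63	Het	repeat
P127-2	G2401A	G418S	.	0.63	Het	repeat
P186-1	C2427T	C426C	.	.	Hom	.
P283-1	C2462T	T438M	12.0	0.01	Hom	.
P229-1	C2489T	S447F	16.9	0.00	Hom	.
P271-1	C2548T	P467S	14.4	0.28	Het	.
P192-1	C2586T	G479G	.	.	Het	.
P190-1	G2777A	G543E	-0.7	1.00	Hom	repeat
P190-3	G2777A	G543E	-0.7	1.00	Hom	repeat
P71-1	G2779A	G544S	-0.4	1.00	Het	.
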