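gene	method	amplicon_bp	end_trim_bp	m2_screened	mutations_total	intron	silent	missense	truncation	reported_kb
Ppd-D1	page_silver	1496	100	512	15	9	1	5	0	44
Ppd-D1	page_etbr	1496	100	512	11	7	1	3	0	60
Ppd-D1	agarose_etbr	1496	100	512	14	8	1	5	0	47
RubiscoA	page_silver+agarose_etbr	946	100	512	7	2	3	2	0	54
RubiscoB	agarose_etbr	959	100	512	9	4	2	3	0	43
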