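gene	all_familial	lp_p_familial	all_sporadic	lp_p_sporadic	p_all_printed	p_lp_p_printed
ACTA2	0	0	0	0	1	1
COL3A1	3	1	0	0	1	1
EFEMP2	5	0	0	0	0.19	1
FBN1	5	0	3	0	1	1
MYH11	9	1	2	0	0.50	1
MYLK	12	0	6	0	1	1
SMAD3	0	0	0	0	1	1
TGFB2	2	0	0	0	0.52	1
TGFBR1	4	0	1	0	0.66	1
TGFBR2	2	0	1	1	1	0.33
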