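study	group	n_cc	n_ct	n_tt	maf_printed	pool_arm	note
Brunelli	AAA	14	32	12	0.483	aaa	
Brunelli	Control	19	35	6	0.392	control	
Strauss	AAA	21	38	4	0.365	aaa	
Strauss	Control	49	20	6	0.231	control	printed MAF does not recompute from the printed cells (32/150 = 0.213)
Jones	AAA	211	169	48	0.310	aaa	
Jones	Control (healthy)	134	122	26	0.309	control	
Jones	Control (CVD)	137	104	30	0.303	control	
Jones	Control (PAD)	106	90	30	0.332	control	
Sofi	AAA	141	217	80	0.430	aaa	
Sofi	Control	166	211	61	0.380	control	
Ferrara	AAA > 60 years	18	23	1	0.298	aaa	
Ferrara	AAA < 60 years	10	33	3	0.424	aaa	
Ferrara	Control	34	10	1	0.133	control	
Current study	AAA total	73	45	12	0.265	aaa	
Current study	AAA familial	48	31	10	0.287	subset	
Current study	AAA sporadic	25	14	2	0.220	subset	
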