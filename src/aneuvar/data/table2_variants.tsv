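gene	transcript	cdna_hgvs	protein_hgvs	consequence	splice_verdict	damaging_count	panel_size	conservation	dbsnp_id	maf_primary	mac_primary	maf_alt	literature_tier	truncation_frame	segregation	gold_class	obs_familial	obs_sporadic
COL3A1	NM_000090.3	c.812G>A	p.Arg271Gln	missense	no_effect	2	5	moderately_conserved:9	rs112185887	0.001	1	0.004	reported_insufficient	not_truncating	not_determined	VUS	1	0
COL3A1	NM_000090.3	c.898-14A>G		intronic	effect	0	0	not_assessed					none	not_truncating	not_determined	VUS	1	0
COL3A1	NM_000090.3	c.1471C>T	p.Arg491X	nonsense	no_effect	0	0	not_assessed					none	out_of_frame	segregates	P	1	0
EFEMP2	NM_016938.3	c.160+17G>T		intronic	no_effect	0	0	not_assessed					none	not_truncating	not_determined	LB	1	0
EFEMP2	NM_016938.3	c.277G>A	p.Gly93Ser	missense	no_effect	0	4	moderately_conserved:10	rs2234462	0.001	3	0.005	none	not_truncating	does_not_segregate	LB	3	0
EFEMP2	NM_016938.3	c.368-4G>A		intronic	no_effect	0	0	not_assessed	rs111550973	0.002	4	0.007	none	not_truncating	does_not_segregate	LB	1	0
EFEMP2	NM_016938.3	c.1047C>T	no-change	synonymous	no_effect	0	0	not_assessed					none	not_truncating	not_determined	LB	1	0
FBN1	NM_000138.3	c.59A>G	p.Tyr20Cys	missense	no_effect	0	4	moderately_conserved:11	rs201309310				reported_insufficient	not_truncating	not_applicable	VUS	0	1
FBN1	NM_000138.3	c.248-17C>G		intronic	no_effect	0	0	not_assessed					none	not_truncating	does_not_segregate	LB	1	0
FBN1	NM_000138.3	c.1108G>A	p.Val370Ile	missense	no_effect	0	5	moderately_conserved:11					none	not_truncating	not_determined	LB	1	0
FBN1	NM_000138.3	c.2260T>C	p.Tyr754His	missense	no_effect	4	5	highly_conserved:11					none	not_truncating	not_determined	VUS	1	0
FBN1	NM_000138.3	c.2895G>A	no-change	synonymous	no_effect	0	0	not_assessed	rs140591				none	not_truncating	not_determined	LB	1	0
FBN1	NM_000138.3	c.3455C>T	p.Ala1152Val	missense	effect	1	5	highly_conserved:11					reported_insufficient	not_truncating	not_applicable	VUS	0	1
FBN1	NM_000138.3	c.6055G>A	p.Glu2019Lys	missense	no_effect	3	5	highly_conserved:11				0.001	reported_insufficient	not_truncating	not_determined	VUS	1	0
FBN1	NM_000138.3	c.7412C>G	p.Pro2471Arg	missense	no_effect	3	5	highly_conserved:11	rs193922233				none	not_truncating	not_applicable	VUS	0	1
MYH11	NM_001040113.1	c.760C>T	p.Arg254Cys	missense	no_effect	3	4	highly_conserved:13	rs150759461	0.001	2	0.008	reported_supported	not_truncating	segregates	LP	1	0
MYH11	NM_001040113.1	c.956A>G	p.Asn319Ser	missense	effect	1	4	highly_conserved:13	rs149964928				none	not_truncating	does_not_segregate	VUS	1	0
MYH11	NM_001040113.1	c.1523G>A	p.Arg508His	missense	no_effect	3	4	highly_conserved:13	rs144244239	0.001	2		none	not_truncating	not_determined	VUS	1	0
MYH11	NM_001040113.1	c.1868C>G	p.Ala623Gly	missense	no_effect	1	4	highly_conserved:13	rs140688587				none	not_truncating	does_not_segregate	LB	1	0
MYH11	NM_001040113.1	c.2881-14C>G		intronic	no_effect	0	0	not_assessed					none	not_truncating	segregates	LB	1	0
MYH11	NM_001040113.1	c.4694C>T	p.Thr1565Met	missense	no_effect	3	4	moderately_conserved:13	rs111854563	0.001	1	0.004	none	not_truncating	twins	VUS	1	0
MYH11	NM_001040113.1	c.5587C>T	no-change	synonymous	no_effect	0	0	not_assessed	rs142639688			0.004	none	not_truncating	not_determined	LB	1	0
MYH11	NM_001040113.1	c.5635-7G>A		intronic	no_effect	0	0	not_assessed	rs202120792	0.001	1		none	not_truncating	not_determined	LB	1	1
MYH11	NM_001040113.1	c.5697G>C	p.Glu1899Asp	missense	no_effect	4	4	highly_conserved:13	rs113964173	0.005	10	0.008	none	not_truncating	does_not_segregate	VUS	1	0
MYH11	NM_001040113.1	c.5808-11_-8del		intronic	effect	0	0	not_assessed					none	not_truncating	not_applicable	VUS	0	1
MYLK	NM_053025.3	c.312T>C	no-change	synonymous	no_effect	0	0	not_assessed	rs147597398				none	not_truncating	twins	LB	1	0
MYLK	NM_053025.3	c.745T>G	p.Ser249Ala	missense	no_effect	2	5	highly_conserved:7					none	not_truncating	not_applicable	VUS	0	1
MYLK	NM_053025.3	c.1314C>T	no-change	synonymous	no_effect	0	0	not_assessed	rs200423954	0.001	2	0.001	none	not_truncating	not_applicable	LB	0	1
MYLK	NM_053025.3	c.1327C>T	p.Pro443Ser	missense	no_effect	4	5	highly_conserved:7	rs35156360	0.006	13	0.014	none	not_truncating	does_not_segregate	VUS	4	0
MYLK	NM_053025.3	c.2101G>A	p.Ala701Thr	missense	no_effect	2	5	highly_conserved:7	rs142835596	0.003	7		none	not_truncating	not_applicable	VUS	0	1
MYLK	NM_053025.3	c.3184G>T	p.Ala1062Ser	missense	no_effect	0	5	highly_conserved:7	rs11558550				none	not_truncating	not_applicable	LB	0	1
MYLK	NM_053025.3	c.3302A>G	p.Lys1101Arg	missense	no_effect	0	5	highly_conserved:7					none	not_truncating	does_not_segregate	LB	1	0
MYLK	NM_053025.3	c.3403G>A	p.Gly1135Arg	missense	no_effect	4	5	highly_conserved:7					none	not_truncating	segregates	VUS	1	0
MYLK	NM_053025.3	c.3583A>G	p.Asn1195Asp	missense	no_effect	3	5	highly_conserved:7					none	not_truncating	not_determined	VUS	1	0
MYLK	NM_053025.3	c.4179C>T	no-change	synonymous	no_effect	0	0	not_assessed					none	not_truncating	does_not_segregate	LB	1	1
MYLK	NM_053025.3	c.4764G>A	no-change	synonymous	no_effect	0	0	not_assessed	rs56056823	0.003	6	0.008	none	not_truncating	not_determined	LB	2	1
MYLK	NM_053025.3	c.4785C>T	no-change	synonymous	no_effect	0	0	not_assessed					none	not_truncating	not_determined	LB	1	0
MYLK	NM_053025.3	c.5079G>A	no-change	synonymous	no_effect	0	0	not_assessed	rs141467675	0.002	5		none	not_truncating	not_determined	LB	1	0
TGFB2	NM_001135599.2	c.272G>A	p.Arg91His	missense	no_effect	3	4	highly_conserved:12	rs10482721	0.001	3	0.005	none	not_truncating	not_determined	VUS	1	0
TGFB2	NM_001135599.2	c.703G>C	p.Val235Leu	missense	no_effect	2	4	highly_conserved:12	rs10482810	0.001	2	0.006	none	not_truncating	not_determined	VUS	1	0
TGFBR1	NM_004612.2	c.15C>T	no-change	synonymous	no_effect	0	0	not_assessed					none	not_truncating	not_determined	LB	1	0
TGFBR1	NM_004612.2	c.214A>T	p.Ile72Leu	missense	no_effect	2	5	highly_conserved:12	rs111513627				none	not_truncating	does_not_segregate	VUS	1	1
TGFBR1	NM_004612.2	c.927G>C	no-change	synonymous	no_effect	0	0	not_assessed					none	not_truncating	not_determined	LB	1	0
TGFBR1	NM_004612.2	c.1125A>C	no-change	synonymous	no_effect	0	0	not_assessed	rs7861780	0.003	6	0.004	none	not_truncating	not_determined	LB	1	0
TGFBR2	NM_001024847.2	c.1137C>T	no-change	synonymous	no_effect	0	0	not_assessed	rs113194608			0.004	none	not_truncating	segregates	LB	1	0
TGFBR2	NM_001024847.2	c.1234G>A	p.Val412Met	missense	no_effect	3	4	highly_conserved:14	rs35766612	0.001	1	0.002	reported_insufficient	not_truncating	twins	VUS	1	0
TGFBR2	NM_001024847.2	c.1573delA	p.Ile525Phefs*18	frameshift	no_effect	0	0	not_assessed					none	out_of_frame	not_applicable	P	0	1
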