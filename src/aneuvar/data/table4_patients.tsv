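patient_id	status	twin_pair_id	genes_tested	variant_keys
T4-01	familial		ACTA2;COL3A1;EFEMP2;FBN1;MYH11;MYLK;SMAD3;TGFB2;TGFBR1;TGFBR2	FBN1:c.1108G>A;TGFBR1:c.15C>T
T4-02	sporadic		ACTA2;COL3A1;EFEMP2;FBN1;MYH11;MYLK;SMAD3;TGFB2;TGFBR1;TGFBR2	FBN1:c.59A>G;MYLK:c.3184G>T
T4-03	familial		ACTA2;COL3A1;EFEMP2;FBN1;MYH11;MYLK;SMAD3;TGFB2;TGFBR1;TGFBR2	FBN1:c.2895G>A;MYLK:c.4764G>A
T4-04	familial	TP1	ACTA2;COL3A1;EFEMP2;FBN1;MYH11;MYLK;SMAD3;TGFB2;TGFBR1;TGFBR2	MYH11:c.4694C>T;TGFBR2:c.1234G>A
T4-05	sporadic		ACTA2;COL3A1;EFEMP2;FBN1;MYH11;MYLK;SMAD3;TGFB2;TGFBR1;TGFBR2	MYH11:c.5635-7G>A;TGFBR2:c.1573delA
T4-06	familial		ACTA2;COL3A1;EFEMP2;FBN1;MYH11;MYLK;SMAD3;TGFB2;TGFBR1;TGFBR2	MYH11:c.5697G>C;TGFBR1:c.1125A>C
T4-07	familial		ACTA2;COL3A1;EFEMP2;FBN1;MYH11;MYLK;SMAD3;TGFB2;TGFBR1;TGFBR2	EFEMP2:c.277G>A;MYLK:c.3302A>G
T4-08	familial		ACTA2;COL3A1;EFEMP2;FBN1;MYH11;MYLK;SMAD3;TGFB2;TGFBR1;TGFBR2	COL3A1:c.812G>A;MYLK:c.1327C>T
T4-09	familial		ACTA2;COL3A1;EFEMP2;FBN1;MYH11;MYLK;SMAD3;TGFB2;TGFBR1;TGFBR2	EFEMP2:c.277G>A;MYH11:c.5587C>T;MYLK:c.1327C>T
T4-10	familial		ACTA2;COL3A1;EFEMP2;FBN1;MYH11;MYLK;SMAD3;TGFB2;TGFBR1;TGFBR2	FBN1:c.248-17C>G;MYH11:c.956A>G
T4-11	familial		ACTA2;COL3A1;EFEMP2;FBN1;MYH11;MYLK;SMAD3;TGFB2;TGFBR1;TGFBR2	EFEMP2:c.1047C>T;EFEMP2:c.277G>A;TGFBR1:c.927G>C
T4-12	familial		ACTA2;COL3A1;EFEMP2;FBN1;MYH11;MYLK;SMAD3;TGFB2;TGFBR1;TGFBR2	FBN1:c.2260T>C;TGFB2:c.272G>A
T4-13	familial		ACTA2;COL3A1;EFEMP2;FBN1;MYH11;MYLK;SMAD3;TGFB2;TGFBR1;TGFBR2	MYLK:c.3583A>G;MYLK:c.5079G>A
F-01	familial		ACTA2;COL3A1;EFEMP2;FBN1;MYH11;MYLK;SMAD3;TGFB2;TGFBR1;TGFBR2	COL3A1:c.898-14A>G
F-02	familial		ACTA2;COL3A1;EFEMP2;FBN1;MYH11;MYLK;SMAD3;TGFB2;TGFBR1;TGFBR2	COL3A1:c.1471C>T
F-03	familial		ACTA2;COL3A1;EFEMP2;FBN1;MYH11;MYLK;SMAD3;TGFB2;TGFBR1;TGFBR2	EFEMP2:c.160+17G>T
F-04	familial		ACTA2;COL3A1;EFEMP2;FBN1;MYH11;MYLK;SMAD3;TGFB2;TGFBR1;TGFBR2	EFEMP2:c.368-4G>A
F-05	familial		ACTA2;COL3A1;EFEMP2;FBN1;MYH11;MYLK;SMAD3;TGFB2;TGFBR1;TGFBR2	FBN1:c.6055G>A
F-06	familial		ACTA2;COL3A1;EFEMP2;FBN1;MYH11;MYLK;SMAD3;TGFB2;TGFBR1;TGFBR2	MYH11:c.760C>T
F-07	familial		ACTA2;COL3A1;EFEMP2;FBN1;MYH11;MYLK;SMAD3;TGFB2;TGFBR1;TGFBR2	MYH11:c.1523G>A
F-08	familial		ACTA2;COL3A1;EFEMP2;FBN1;MYH11;MYLK;SMAD3;TGFB2;TGFBR1;TGFBR2	MYH11:c.1868C>G
F-09	familial		ACTA2;COL3A1;EFEMP2;FBN1;MYH11;MYLK;SMAD3;TGFB2;TGFBR1;TGFBR2	MYH11:c.2881-14C>G
F-10	familial		ACTA2;COL3A1;EFEMP2;FBN1;MYH11;MYLK;SMAD3;TGFB2;TGFBR1;TGFBR2	MYH11:c.5635-7G>A
F-11	familial	TP2	ACTA2;COL3A1;EFEMP2;FBN1;MYH11;MYLK;SMAD3;TGFB2;TGFBR1;TGFBR2	MYLK:c.312T>C
F-12	familial		ACTA2;COL3A1;EFEMP2;FBN1;MYH11;MYLK;SMAD3;TGFB2;TGFBR1;TGFBR2	MYLK:c.1327C>T
F-13	familial		ACTA2;COL3A1;EFEMP2;FBN1;MYH11;MYLK;SMAD3;TGFB2;TGFBR1;TGFBR2	MYLK:c.1327C>T
F-14	familial		ACTA2;COL3A1;EFEMP2;FBN1;MYH11;MYLK;SMAD3;TGFB2;TGFBR1;TGFBR2	MYLK:c.3403G>A
F-15	familial		ACTA2;COL3A1;EFEMP2;FBN1;MYH11;MYLK;SMAD3;TGFB2;TGFBR1;TGFBR2	MYLK:c.4179C>T
F-16	familial		ACTA2;COL3A1;EFEMP2;FBN1;MYH11;MYLK;SMAD3;TGFB2;TGFBR1;TGFBR2	MYLK:c.4764G>A
F-17	familial		ACTA2;COL3A1;EFEMP2;FBN1;MYH11;MYLK;SMAD3;TGFB2;TGFBR1;TGFBR2	MYLK:c.4785C>T
F-18	familial		ACTA2;COL3A1;EFEMP2;FBN1;MYH11;MYLK;SMAD3;TGFB2;TGFBR1;TGFBR2	TGFB2:c.703G>C
F-19	familial		ACTA2;COL3A1;EFEMP2;FBN1;MYH11;MYLK;SMAD3;TGFB2;TGFBR1;TGFBR2	TGFBR1:c.214A>T
F-20	familial		ACTA2;COL3A1;EFEMP2;FBN1;MYH11;MYLK;SMAD3;TGFB2;TGFBR1;TGFBR2	TGFBR2:c.1137C>T
S-01	sporadic		ACTA2;COL3A1;EFEMP2;FBN1;MYH11;MYLK;SMAD3;TGFB2;TGFBR1;TGFBR2	FBN1:c.3455C>T
S-02	sporadic		ACTA2;COL3A1;EFEMP2;FBN1;MYH11;MYLK;SMAD3;TGFB2;TGFBR1;TGFBR2	FBN1:c.7412C>G
S-03	sporadic		ACTA2;COL3A1;EFEMP2;FBN1;MYH11;MYLK;SMAD3;TGFB2;TGFBR1;TGFBR2	MYH11:c.5808-11_-8del
S-04	sporadic		ACTA2;COL3A1;EFEMP2;FBN1;MYH11;MYLK;SMAD3;TGFB2;TGFBR1;TGFBR2	MYLK:c.745T>G
S-05	sporadic		ACTA2;COL3A1;EFEMP2;FBN1;MYH11;MYLK;SMAD3;TGFB2;TGFBR1;TGFBR2	MYLK:c.1314C>T
S-06	sporadic		ACTA2;COL3A1;EFEMP2;FBN1;MYH11;MYLK;SMAD3;TGFB2;TGFBR1;TGFBR2	MYLK:c.2101G>A
S-07	sporadic		ACTA2;COL3A1;EFEMP2;FBN1;MYH11;MYLK;SMAD3;TGFB2;TGFBR1;TGFBR2	MYLK:c.4179C>T
S-08	sporadic		ACTA2;COL3A1;EFEMP2;FBN1;MYH11;MYLK;SMAD3;TGFB2;TGFBR1;TGFBR2	MYLK:c.4764G>A
S-09	sporadic		ACTA2;COL3A1;EFEMP2;FBN1;MYH11;MYLK;SMAD3;TGFB2;TGFBR1;TGFBR2	TGFBR1:c.214A>T
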