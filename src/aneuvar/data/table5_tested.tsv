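gene	n_familial	n_sporadic
ACTA2	92	47
COL3A1	82	40
EFEMP2	65	24
FBN1	85	42
MYH11	90	43
MYLK	90	46
SMAD3	94	48
TGFB2	40	25
TGFBR1	93	48
TGFBR2	94	46
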