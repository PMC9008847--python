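name	iupac	category
W-box	YTGACY	stress
Box4	ATTAAT	light
G-box	CACGTG	light
Sp1	GGGCGG	light
ACE	GACACGTATG	light
GT1-motif	GGTTAA	light
CCGTCC-box	CCGTCC	development
CAT-box	GCCACT	development
GCN4-motif	TGAGTCA	development
circadian	CAANNNNATC	development
ERE	ATTTCAAA	hormone
ABRE	ACGTG	hormone
CGTCA-motif	CGTCA	hormone
TGACG-motif	TGACG	hormone
GARE-motif	TCTGTTG	hormone
TATC-box	TATCCCA	hormone
P-box	CCTTTTG	hormone
TCA-element	CCATCTTTTT	hormone
SARE	TTCGACCATCTT	hormone
LTR	CCGAAA	stress
DRE-core	GCCGAC	stress
WUN-motif	AAATTTCCT	stress
TGA-element	AACGAC	hormone
AuxRR-core	GGTCCAT	hormone
ARE	AAACCA	stress
MBS	CAACTG	stress
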