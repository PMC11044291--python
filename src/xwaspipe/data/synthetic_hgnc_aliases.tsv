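ALIAS	CANONICAL
KIAA0101	PCLAF
C11orf30	EMSY
SNX19	SNX19
FAM19A2	TAFA2
C2orf47	MAIP1
KIAA1324	ELAPOR1
C9orf72	C9orf72
HIST1H2BC	H2BC4
WHSC1	NSD2
MLL2	KMT2D
B3GNT1	B4GAT1
SEPT4	SEPTIN4
MARCH1	MARCHF1
AES	TLE5
GARS	GARS1
ADCK3	COQ8A
TMEM27	CLTRN
FAM46A	TENT5A
CASC4	GOLM2
KIAA0196	WASHC5
ZNF259	ZPR1
SELO	SELENOO
ATP5A1	ATP5F1A
GPR56	ADGRG1
PVRL2	NECTIN2
DIRC2	SLC49A4
CCDC101	SGF29
ERBB2IP	ERBIN
PAK7	PAK5
HN1	JPT1
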