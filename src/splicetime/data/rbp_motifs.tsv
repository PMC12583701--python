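# Curated IUPAC consensus elements for 46 RBPs with public eCLIP-derived
# motif classes (oRNAment/CLIPdb-style sources). DNA alphabet (U -> T).
# One row per consensus; RBPs may carry several.
rbp_name	consensus	source
RBFOX1	TGCATG	oRNAment-like
RBFOX2	TGCATG	oRNAment-like
RBFOX3	TGCATG	oRNAment-like
NOVA1	YCAYC	CLIPdb-like
NOVA2	YCAYC	CLIPdb-like
PTBP1	TTCTTC	oRNAment-like
PTBP2	TTCTTC	oRNAment-like
QKI	ACTAAY	oRNAment-like
KHDRBS1	ATAAAA	CLIPdb-like
KHDRBS2	ATAAAA	CLIPdb-like
KHDRBS3	AWTAAA	CLIPdb-like
ELAVL1	TTTWTTT	oRNAment-like
ELAVL2	TTTWTTT	oRNAment-like
ELAVL3	TTTWTTT	oRNAment-like
ELAVL4	TTTWTTT	oRNAment-like
HNRNPC	TTTTTT	CLIPdb-like
HNRNPK	CCCWCC	CLIPdb-like
HNRNPL	ACACAC	CLIPdb-like
HNRNPA1	TAGGGW	oRNAment-like
HNRNPA2B1	GGTAGG	oRNAment-like
HNRNPM	GGTTGG	CLIPdb-like
HNRNPU	WGTATT	CLIPdb-like
TIA1	TTTTTW	oRNAment-like
TIAL1	TTTTTW	oRNAment-like
U2AF1	YAGGT	CLIPdb-like
U2AF2	YYYYYC	CLIPdb-like
TARDBP	TGTGTG	oRNAment-like
FUS	GGTGGT	CLIPdb-like
TAF15	GGTAAG	CLIPdb-like
EWSR1	GGGGWG	CLIPdb-like
MBNL1	YGCYGC	oRNAment-like
MBNL2	YGCYGC	oRNAment-like
CELF1	GTGTTG	oRNAment-like
CELF2	GTGTTG	oRNAment-like
KHSRP	GTTGTT	CLIPdb-like
MATR3	ATCTTC	CLIPdb-like
PCBP1	CCCTCC	CLIPdb-like
PCBP2	CCCTCC	CLIPdb-like
IGF2BP1	ACACCC	CLIPdb-like
IGF2BP2	ACACCC	CLIPdb-like
IGF2BP3	ACACCC	CLIPdb-like
SFPQ	TGTAAG	CLIPdb-like
SRSF1	GGAGGA	oRNAment-like
SRSF7	ACGACG	oRNAment-like
TRA2B	GAAGAA	oRNAment-like
SRRM4	TGCTGC	CLIPdb-like
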