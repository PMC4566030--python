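name	pattern	source
ESRP1	UGGUGG	known_rbp_set
PTBP1	UCUUC	known_rbp_set
PTBP1_CU	CUCUCU	known_rbp_set
MBNL1	YGCY	known_rbp_set
QKI	ACUAAY	known_rbp_set
SFPQ	UGUAA	known_rbp_set
RBM38	UGUGUG	known_rbp_set
RBM24	GUGUG	known_rbp_set
SRSF10	AGAGA	known_rbp_set
BRUNOL6	UGUU	known_rbp_set
RBFOX2	UGCAUG	known_rbp_set
NOVA1	YCAY	known_rbp_set
HNRNPA1	UAGGGW	known_rbp_set
HNRNPC	UUUUU	known_rbp_set
HNRNPF	GGGA	known_rbp_set
HNRNPL	ACACA	known_rbp_set
SRSF1	RGAAGAAC	known_rbp_set
SRSF2	SSNG	known_rbp_set
TIA1	UUUUA	known_rbp_set
U2AF2	UUUYC	known_rbp_set
CPEB1	UUUUAU	known_rbp_set
KHDRBS1	AUAAA	known_rbp_set
ELAVL1	UUKRUUU	known_rbp_set
PCBP1	CCCUCCC	known_rbp_set
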