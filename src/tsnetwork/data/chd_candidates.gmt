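CHD_candidates	congenital heart disease candidate genes	PLN	NPPA	ANKRD1	MYH6	MYH7	ACTC1	CACNA1C	TBX20	HEY2	SLC8A1	RYR2	MYOCD	GJA1	ATP2A2	FBN2	SRPX	SCN5A	TBX5	HAND2	KCNJ2
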