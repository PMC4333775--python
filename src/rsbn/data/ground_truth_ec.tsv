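source	target	weight
SN	aDMN	1.42
SN	pDMN	0.85
HVN	PVN	0.8
PSMN	PVN	0.37
aDMN	DAN	0.32
VMN	DAN	0.43
SN	CEN	0.41
SN	PSMN	0.35
HVN	aDMN	0.28
PSMN	VMN	0.33
CEN	PSMN	0.24
HVN	CEN	0.21
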