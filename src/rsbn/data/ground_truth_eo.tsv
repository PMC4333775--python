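source	target	weight
SN	aDMN	1.59
SN	pDMN	0.87
HVN	PVN	0.67
PSMN	PVN	0.34
aDMN	DAN	-0.21
CEN	DAN	0.44
SN	PVN	0.36
PSMN	DAN	0.33
VMN	CEN	0.31
pDMN	DAN	0.30
PVN	DAN	0.29
aDMN	VMN	0.16
CEN	PVN	-0.16
VMN	PSMN	0.35
PSMN	CEN	0.19
CEN	HVN	0.14
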