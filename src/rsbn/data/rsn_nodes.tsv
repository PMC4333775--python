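name	region	x	y	z	radius_mm	t_value	r_value
PVN	Lingual_R	6	-84	-3	6	18.75	0.52
HVN	Occipital_Sup_R	24	-102	9	6	19.24	0.34
PSMN	Supp_Motor_Area_R	3	-15	69	6	17.98	0.37
VMN	Postcentral_R	60	-6	33	6	18.88	0.50
DAN	Parietal_Sup_L	-18	-75	51	6	19.68	
CEN	Frontal_Inf_Tri_R	51	27	27	6	14.33	0.46
aDMN	Frontal_Sup_Medial_L	0	54	15	6	18.59	0.55
pDMN	Cingulum_Mid_R	3	-30	30	6	25.31	0.64
SN	Cingulum_Ant_L	-9	39	-3	6	24.27	0.50
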