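id	region	n_voxels	t_value	x	y	z
1	Cuneus_L	223	-7.55	3	78	24
2	Lingual_R	126	7.04	18	51	3
3	Calcarine_L	244	6.89	12	66	9
4	Cuneus_R	188	6.87	6	78	27
5	Calcarine_R	127	6.62	18	54	6
6	Lingual_L	117	6.33	9	63	6
7	Precuneus_R	123	5.82	6	66	24
8	Cingulum_Post_L	72	5.65	0	45	30
9	Precuneus_L	96	5.61	6	54	30
10	Temporal_Sup_R	72	5.82	60	27	12
11	Parietal_Inf_R	78	5.95	57	36	48
12	Frontal_Sup_R	65	6.15	18	12	63
13	Occipital_Mid_L	85	6.19	9	105	3
14	Postcentral_L	111	6.19	57	0	18
15	Frontal_Mid_R	237	6.21	30	45	24
16	SupraMarginal_R	151	6.33	48	36	39
17	Precentral_L	128	6.75	18	21	69
18	Insula_R	130	6.87	30	18	6
19	Cingulum_Mid_R	126	7.33	9	15	45
20	Temporal_Sup_L	115	7.57	51	39	18
21	Precentral_R	92	7.68	57	9	18
22	Supp_Motor_Area_R	240	7.96	3	3	66
23	Rolandic_Oper_R	93	8.14	54	6	15
24	Frontal_Inf_Oper_R	166	8.49	51	9	12
25	Supp_Motor_Area_L	307	8.79	3	0	66
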