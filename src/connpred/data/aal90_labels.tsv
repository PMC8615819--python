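index	name	abbreviation
1	Left precentral gyrus	Precentral_L
2	Right precentral gyrus	Precentral_R
3	Left superior frontal gyrus, dorsolateral	Frontal_Sup_L
4	Right superior frontal gyrus, dorsolateral	Frontal_Sup_R
5	Left superior frontal gyrus, orbital part	Frontal_Sup_Orb_L
6	Right superior frontal gyrus, orbital part	Frontal_Sup_Orb_R
7	Left middle frontal gyrus	Frontal_Mid_L
8	Right middle frontal gyrus	Frontal_Mid_R
9	Left middle frontal gyrus, orbital part	Frontal_Mid_Orb_L
10	Right middle frontal gyrus, orbital part	Frontal_Mid_Orb_R
11	Left inferior frontal gyrus, opercular part	Frontal_Inf_Oper_L
12	Right inferior frontal gyrus, opercular part	Frontal_Inf_Oper_R
13	Left inferior frontal gyrus, triangular part	Frontal_Inf_Tri_L
14	Right inferior frontal gyrus, triangular part	Frontal_Inf_Tri_R
15	Left inferior frontal gyrus, orbital part	Frontal_Inf_Orb_L
16	Right inferior frontal gyrus, orbital part	Frontal_Inf_Orb_R
17	Left rolandic operculum	Rolandic_Oper_L
18	Right rolandic operculum	Rolandic_Oper_R
19	Left supplementary motor area	Supp_Motor_Area_L
20	Right supplementary motor area	Supp_Motor_Area_R
21	Left olfactory cortex	Olfactory_L
22	Right olfactory cortex	Olfactory_R
23	Left superior frontal gyrus, medial part	Frontal_Sup_Medial_L
24	Right superior frontal gyrus, medial part	Frontal_Sup_Medial_R
25	Left superior frontal gyrus, medial orbital	Frontal_Med_Orb_L
26	Right superior frontal gyrus, medial orbital	Frontal_Med_Orb_R
27	Left gyrus rectus	Rectus_L
28	Right gyrus rectus	Rectus_R
29	Left insula	Insula_L
30	Right insula	Insula_R
31	Left anterior cingulate gyrus	Cingulum_Ant_L
32	Right anterior cingulate gyrus	Cingulum_Ant_R
33	Left median cingulate gyrus	Cingulum_Mid_L
34	Right median cingulate gyrus	Cingulum_Mid_R
35	Left posterior cingulate gyrus	Cingulum_Post_L
36	Right posterior cingulate gyrus	Cingulum_Post_R
37	Left hippocampus	Hippocampus_L
38	Right hippocampus	Hippocampus_R
39	Left parahippocampal gyrus	ParaHippocampal_L
40	Right parahippocampal gyrus	ParaHippocampal_R
41	Left amygdala	Amygdala_L
42	Right amygdala	Amygdala_R
43	Left calcarine fissure and surrounding cortex	Calcarine_L
44	Right calcarine fissure and surrounding cortex	Calcarine_R
45	Left cuneus	Cuneus_L
46	Right cuneus	Cuneus_R
47	Left lingual gyrus	Lingual_L
48	Right lingual gyrus	Lingual_R
49	Left superior occipital gyrus	Occipital_Sup_L
50	Right superior occipital gyrus	Occipital_Sup_R
51	Left middle occipital gyrus	Occipital_Mid_L
52	Right middle occipital gyrus	Occipital_Mid_R
53	Left inferior occipital gyrus	Occipital_Inf_L
54	Right inferior occipital gyrus	Occipital_Inf_R
55	Left fusiform gyrus	Fusiform_L
56	Right fusiform gyrus	Fusiform_R
57	Left postcentral gyrus	Postcentral_L
58	Right postcentral gyrus	Postcentral_R
59	Left superior parietal gyrus	Parietal_Sup_L
60	Right superior parietal gyrus	Parietal_Sup_R
61	Left inferior parietal lobule	Parietal_Inf_L
62	Right inferior parietal lobule	Parietal_Inf_R
63	Left supramarginal gyrus	SupraMarginal_L
64	Right supramarginal gyrus	SupraMarginal_R
65	Left angular gyrus	Angular_L
66	Right angular gyrus	Angular_R
67	Left precuneus	Precuneus_L
68	Right precuneus	Precuneus_R
69	Left paracentral lobule	Paracentral_Lobule_L
70	Right paracentral lobule	Paracentral_Lobule_R
71	Left caudate nucleus	Caudate_L
72	Right caudate nucleus	Caudate_R
73	Left putamen	Putamen_L
74	Right putamen	Putamen_R
75	Left pallidum	Pallidum_L
76	Right pallidum	Pallidum_R
77	Left thalamus	Thalamus_L
78	Right thalamus	Thalamus_R
79	Left Heschl gyrus	Heschl_L
80	Right Heschl gyrus	Heschl_R
81	Left superior temporal gyrus	Temporal_Sup_L
82	Right superior temporal gyrus	Temporal_Sup_R
83	Left temporal pole, superior temporal gyrus	Temporal_Pole_Sup_L
84	Right temporal pole, superior temporal gyrus	Temporal_Pole_Sup_R
85	Left middle temporal gyrus	Temporal_Mid_L
86	Right middle temporal gyrus	Temporal_Mid_R
87	Left temporal pole, middle temporal gyrus	Temporal_Pole_Mid_L
88	Right temporal pole, middle temporal gyrus	Temporal_Pole_Mid_R
89	Left inferior temporal gyrus	Temporal_Inf_L
90	Right inferior temporal gyrus	Temporal_Inf_R
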