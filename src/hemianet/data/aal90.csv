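index,label,hemisphere,lobe
1,Precentral_L,L,Frontal
2,Precentral_R,R,Frontal
3,Frontal_Sup_L,L,Frontal
4,Frontal_Sup_R,R,Frontal
5,Frontal_Sup_Orb_L,L,Frontal
6,Frontal_Sup_Orb_R,R,Frontal
7,Frontal_Mid_L,L,Frontal
8,Frontal_Mid_R,R,Frontal
9,Frontal_Mid_Orb_L,L,Frontal
10,Frontal_Mid_Orb_R,R,Frontal
11,Frontal_Inf_Oper_L,L,Frontal
12,Frontal_Inf_Oper_R,R,Frontal
13,Frontal_Inf_Tri_L,L,Frontal
14,Frontal_Inf_Tri_R,R,Frontal
15,Frontal_Inf_Orb_L,L,Frontal
16,Frontal_Inf_Orb_R,R,Frontal
17,Rolandic_Oper_L,L,Frontal
18,Rolandic_Oper_R,R,Frontal
19,Supp_Motor_Area_L,L,Frontal
20,Supp_Motor_Area_R,R,Frontal
21,Olfactory_L,L,Frontal
22,Olfactory_R,R,Frontal
23,Frontal_Sup_Medial_L,L,Frontal
24,Frontal_Sup_Medial_R,R,Frontal
25,Frontal_Med_Orb_L,L,Frontal
26,Frontal_Med_Orb_R,R,Frontal
27,Rectus_L,L,Frontal
28,Rectus_R,R,Frontal
29,Insula_L,L,Other
30,Insula_R,R,Other
31,Cingulum_Ant_L,L,Other
32,Cingulum_Ant_R,R,Other
33,Cingulum_Mid_L,L,Other
34,Cingulum_Mid_R,R,Other
35,Cingulum_Post_L,L,Other
36,Cingulum_Post_R,R,Other
37,Hippocampus_L,L,Other
38,Hippocampus_R,R,Other
39,ParaHippocampal_L,L,Other
40,ParaHippocampal_R,R,Other
41,Amygdala_L,L,Other
42,Amygdala_R,R,Other
43,Calcarine_L,L,Occipital
44,Calcarine_R,R,Occipital
45,Cuneus_L,L,Occipital
46,Cuneus_R,R,Occipital
47,Lingual_L,L,Occipital
48,Lingual_R,R,Occipital
49,Occipital_Sup_L,L,Occipital
50,Occipital_Sup_R,R,Occipital
51,Occipital_Mid_L,L,Occipital
52,Occipital_Mid_R,R,Occipital
53,Occipital_Inf_L,L,Occipital
54,Occipital_Inf_R,R,Occipital
55,Fusiform_L,L,Temporal
56,Fusiform_R,R,Temporal
57,Postcentral_L,L,Parietal
58,Postcentral_R,R,Parietal
59,Parietal_Sup_L,L,Parietal
60,Parietal_Sup_R,R,Parietal
61,Parietal_Inf_L,L,Parietal
62,Parietal_Inf_R,R,Parietal
63,SupraMarginal_L,L,Parietal
64,SupraMarginal_R,R,Parietal
65,Angular_L,L,Parietal
66,Angular_R,R,Parietal
67,Precuneus_L,L,Parietal
68,Precuneus_R,R,Parietal
69,Paracentral_Lobule_L,L,Frontal
70,Paracentral_Lobule_R,R,Frontal
71,Caudate_L,L,Other
72,Caudate_R,R,Other
73,Putamen_L,L,Other
74,Putamen_R,R,Other
75,Pallidum_L,L,Other
76,Pallidum_R,R,Other
77,Thalamus_L,L,Other
78,Thalamus_R,R,Other
79,Heschl_L,L,Temporal
80,Heschl_R,R,Temporal
81,Temporal_Sup_L,L,Temporal
82,Temporal_Sup_R,R,Temporal
83,Temporal_Pole_Sup_L,L,Temporal
84,Temporal_Pole_Sup_R,R,Temporal
85,Temporal_Mid_L,L,Temporal
86,Temporal_Mid_R,R,Temporal
87,Temporal_Pole_Mid_L,L,Temporal
88,Temporal_Pole_Mid_R,R,Temporal
89,Temporal_Inf_L,L,Temporal
90,Temporal_Inf_R,R,Temporal
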