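# Canonical 77-region grey-matter parcellation for regional FDG-PET analysis.
# Region names follow the Hammers adult maximum-probability atlas naming convention
# (38 bilateral pairs + brainstem); composite assignments follow the usual PMOD-style
# lobar grouping. Volumes are indicative round numbers used only as default weights
# for volume-weighted means; they are NOT measured atlas volumes.
label,name,composite,volume_mm3
1,anterior_temporal_lobe_medial_L,temporal,5000
2,anterior_temporal_lobe_medial_R,temporal,5000
3,anterior_temporal_lobe_lateral_L,temporal,7000
4,anterior_temporal_lobe_lateral_R,temporal,7000
5,superior_temporal_gyrus_anterior_L,temporal,3000
6,superior_temporal_gyrus_anterior_R,temporal,3000
7,superior_temporal_gyrus_posterior_L,temporal,8000
8,superior_temporal_gyrus_posterior_R,temporal,8000
9,middle_inferior_temporal_gyrus_L,temporal,20000
10,middle_inferior_temporal_gyrus_R,temporal,20000
11,fusiform_gyrus_L,temporal,8000
12,fusiform_gyrus_R,temporal,8000
13,posterior_temporal_lobe_L,temporal,20000
14,posterior_temporal_lobe_R,temporal,20000
15,superior_frontal_gyrus_L,frontal,20000
16,superior_frontal_gyrus_R,frontal,20000
17,middle_frontal_gyrus_L,frontal,25000
18,middle_frontal_gyrus_R,frontal,25000
19,inferior_frontal_gyrus_L,frontal,12000
20,inferior_frontal_gyrus_R,frontal,12000
21,precentral_gyrus_L,frontal,15000
22,precentral_gyrus_R,frontal,15000
23,straight_gyrus_L,frontal,3000
24,straight_gyrus_R,frontal,3000
25,anterior_orbital_gyrus_L,frontal,2500
26,anterior_orbital_gyrus_R,frontal,2500
27,medial_orbital_gyrus_L,frontal,4000
28,medial_orbital_gyrus_R,frontal,4000
29,lateral_orbital_gyrus_L,frontal,3000
30,lateral_orbital_gyrus_R,frontal,3000
31,posterior_orbital_gyrus_L,frontal,4000
32,posterior_orbital_gyrus_R,frontal,4000
33,subgenual_frontal_cortex_L,frontal,1200
34,subgenual_frontal_cortex_R,frontal,1200
35,subcallosal_area_L,frontal,800
36,subcallosal_area_R,frontal,800
37,postcentral_gyrus_L,parietal,12000
38,postcentral_gyrus_R,parietal,12000
39,superior_parietal_gyrus_L,parietal,15000
40,superior_parietal_gyrus_R,parietal,15000
41,inferolateral_parietal_lobe_L,parietal,25000
42,inferolateral_parietal_lobe_R,parietal,25000
43,precuneus_L,parietal,9000
44,precuneus_R,parietal,9000
45,lingual_gyrus_L,occipital,7000
46,lingual_gyrus_R,occipital,7000
47,cuneus_L,occipital,5000
48,cuneus_R,occipital,5000
49,lateral_occipital_lobe_L,occipital,20000
50,lateral_occipital_lobe_R,occipital,20000
51,insula_L,insula,10000
52,insula_R,insula,10000
53,hippocampus_L,limbic,3500
54,hippocampus_R,limbic,3500
55,amygdala_L,limbic,1800
56,amygdala_R,limbic,1800
57,parahippocampal_ambient_gyrus_L,limbic,4000
58,parahippocampal_ambient_gyrus_R,limbic,4000
59,anterior_cingulate_gyrus_L,limbic,9000
60,anterior_cingulate_gyrus_R,limbic,9000
61,posterior_cingulate_gyrus_L,limbic,6000
62,posterior_cingulate_gyrus_R,limbic,6000
63,caudate_nucleus_L,basal_ganglia,4000
64,caudate_nucleus_R,basal_ganglia,4000
65,nucleus_accumbens_L,basal_ganglia,600
66,nucleus_accumbens_R,basal_ganglia,600
67,putamen_L,basal_ganglia,4500
68,putamen_R,basal_ganglia,4500
69,pallidum_L,basal_ganglia,1300
70,pallidum_R,basal_ganglia,1300
71,substantia_nigra_L,basal_ganglia,600
72,substantia_nigra_R,basal_ganglia,600
73,thalamus_L,,7500
74,thalamus_R,,7500
75,cerebellum_L,cerebellum,55000
76,cerebellum_R,cerebellum,55000
77,brainstem,,22000
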