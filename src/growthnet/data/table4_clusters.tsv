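cluster_name	n_growth_genes	growth_fold_enrichment	n_high_candidates	high_fold_enrichment	high_candidate_genes	n_medium_candidates	medium_fold_enrichment
Skeletal system development	996	3.2	11	0.7	CPZ,EDEM3,FBRS,IFT81,KCND1,PLXNA3,RASA3,SLC7A8,UBR4,USP45,ZFHX3	49	0.9
Appendage development	894	2.8	9	0.5	CPZ,EDEM3,FBRS,IFT81,KCND1,PLXNA3,RASA3,SLC7A8,ZFHX3	32	1.4
Ciliopathy	845	3.6	9	1.5	EDEM3,IFT81,KCND1,PLXNA3,RASA3,SLC7A8,UBR4,USP45,ZFHX3	38	1.2
Single-organism metabolic process	740	3.7	5	0.1	CPZ,EDEM3,KCND1,RASA3,SLC7A8	28	0.6
Catalytic activity	721	1.7	6	0.2	CPZ,EDEM3,RASA3,UBR4,USP45,ZFHX3	33	1.8
Chemical homeostasis	629	1.9	5	1.0	EDEM3,IFT81,KCND1,RASA3,SLC7A8	22	0.8
Extracellular matrix	521	1.4	5	1.1	CPZ,EDEM3,FBRS,PLXNA3,SLC7A8	23	0.9
Peroxisome biogenesis disorder	361	6.0	2	0.1	IFT81,SLC7A8	9	0.3
Ossification	284	5.6	2	0.4	CPZ,EDEM3	5	1.6
Chromatin binding	265	2.9	2	0.2	PLXNA3,ZFHX3	12	0.8
Proteoglycan metabolic process	196	3.0	1	0.5	EDEM3	9	0.8
Oxidoreductase activity	190	2.7	0			2	0.1
Congenital hypothyroidism	184	4.2	0			0
Diamond-Blackfan anemia	182	3.5	0			5	0.4
Striated muscle tissue development	180	2.5	2	0.9	KCND1,RASA3	3	0.4
Single-organism carbohydrate catabolic process	155	2.4	0			4	1.8
DNA repair	141	4.4	2	0.6		4	2.5
Ichthyosis	139	3.9	3	0.5	EDEM3	2	0.6
Head development	125	2.8	2	2.8	PLXNA3,ZFHX3	2	0.3
Hydrolase activity, acting on ester bonds	116	1.9	1	1.6	EDEM3	1	0.1
Behavior	105	2.3	1	0.3	ZFHX3	1	0.2
Sensory organ development	101	4.0	0			2	4.3
Anatomical structure homeostasis	99	3.1	0			0
Sulfur compound metabolic process	83	3.5	0			2	0.3
Tissue remodeling	83	2.4	1	0.7	RASA3	0
Positive regulation of epithelial cell proliferation	78	3.2	1	1.5	PLXNA3	1	0.4
Response to nutrient levels	63	3.4	0			1	0.3
Bone morphogenesis	60	6.3	0			1	2.4
Reactive oxygen species metabolic process	52	2.6	0			0
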