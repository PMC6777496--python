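gene	n_families	n_class_V	n_class_IV	n_class_III	category_count	score_min	score_max	tally_ambiguous	previously_reported
CPZ	3	0	0	3	1	3	3	1	0
EDEM3	2	0	0	2	3	3	3	1	0
FBRS	3	0	2	1	3	3	3	1	0
IFT81	2	0	0	2	2	3	3	1	1
KCND1	2	0	0	2	1	3	3	1	0
LAMA5	8	0	4	4	4	3	3	0	0
MED24	2	1	1	0	5	4	4	0	0
PLXNA3	2	0	0	2	5	3	3	1	0
RASA3	2	1	1	0	4	3	4	0	0
SLC7A8	2	0	0	2	3	3	3	1	0
UBR4	6	0	5	1	4	2	3	0	0
USP45	4	1	2	1	2	2	4	0	0
ZFHX3	2	0	1	1	5	3	4	1	0
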