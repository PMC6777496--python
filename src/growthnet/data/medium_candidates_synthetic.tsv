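gene	n_families	n_class_V	n_class_IV	n_class_III	category_count	score_min	score_max	tally_ambiguous	previously_reported
AMMECR1	1	0	1	0	2	2	2	1	1
BRD4	1	0	0	1	3	2	2	1	1
FZD2	2	0	1	1	1	1	2	1	1
LZTR1	2	0	1	1	2	1	2	1	1
ZBED4	1	1	0	0	2	3	3	1	1
SYNCAND01	1	0	1	0	3	3	3	0	0
SYNCAND02	1	0	0	1	4	2	2	0	0
SYNCAND03	1	0	1	0	1	2	2	0	0
SYNCAND04	1	1	0	0	0	3	3	0	0
SYNCAND05	1	0	0	1	2	1	1	0	0
SYNCAND06	1	0	1	0	5	3	3	0	0
SYNCAND07	1	0	0	1	3	2	2	0	0
SYNCAND08	1	0	1	0	2	2	2	0	0
SYNCAND09	1	0	0	2	1	1	1	0	0
SYNCAND10	1	0	1	0	4	3	3	0	0
SYNCAND11	1	0	0	1	1	1	1	0	0
SYNCAND12	1	1	0	0	3	4	4	0	0
SYNCAND13	1	0	1	0	2	2	2	0	0
SYNCAND14	1	0	0	1	1	1	1	0	0
SYNCAND15	1	0	1	0	3	3	3	0	0
SYNCAND16	1	0	0	1	2	1	1	0	0
SYNCAND17	1	0	1	0	0	2	2	0	0
SYNCAND18	1	0	0	1	5	2	2	0	0
SYNCAND19	1	0	1	0	1	2	2	0	0
SYNCAND20	1	1	0	0	2	3	3	0	0
SYNCAND21	1	0	0	1	3	2	2	0	0
SYNCAND22	1	0	1	0	2	2	2	0	0
SYNCAND23	1	0	0	1	1	1	1	0	0
SYNCAND24	1	0	1	0	4	3	3	0	0
SYNCAND25	1	0	0	1	1	1	1	0	0
SYNCAND26	1	0	1	0	3	3	3	0	0
SYNCAND27	1	0	0	1	2	1	1	0	0
SYNCAND28	1	0	1	0	1	2	2	0	0
SYNCAND29	1	1	0	0	0	3	3	0	0
SYNCAND30	1	0	0	1	3	2	2	0	0
SYNCAND31	1	0	1	0	2	2	2	0	0
SYNCAND32	1	0	0	1	1	1	1	0	0
SYNCAND33	1	0	1	0	5	3	3	0	0
SYNCAND34	1	0	0	1	2	1	1	0	0
SYNCAND35	1	0	1	0	3	3	3	0	0
SYNCAND36	1	0	0	1	1	1	1	0	0
SYNCAND37	1	0	1	0	1	2	2	0	0
SYNCAND38	1	1	0	0	4	4	4	0	0
SYNCAND39	1	0	0	1	2	1	1	0	0
SYNCAND40	1	0	1	0	3	3	3	0	0
SYNCAND41	1	0	0	1	1	1	1	0	0
SYNCAND42	1	0	1	0	2	2	2	0	0
SYNCAND43	1	0	0	1	3	2	2	0	0
SYNCAND44	1	0	1	0	0	2	2	0	0
SYNCAND45	1	0	0	1	4	2	2	0	0
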