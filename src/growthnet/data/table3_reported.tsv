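gene	confidence	n_families	n_class_V	n_class_IV	n_class_III	tally_ambiguous
IFT81	high	2	0	0	2	1
AMMECR1	medium	1	0	1	0	1
BRD4	medium	1	0	0	1	1
FZD2	medium	2	0	1	1	1
LZTR1	medium	2	0	1	1	1
ZBED4	medium	1	1	0	0	1
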