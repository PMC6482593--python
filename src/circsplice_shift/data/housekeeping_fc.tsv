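gene	fold_change
C1orf43	0.97
CHMP2A	1
GAPDH	1
EMC7	0.98
GPI	1
PSMB2	0.98
PSMB4	1.02
RAB7A	0.98
SNRPD3	1
VPS29	1.04
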