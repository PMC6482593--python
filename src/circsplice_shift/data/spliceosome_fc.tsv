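gene	fold_change
FUS	0.68
PCBP2	0.68
RBM7	0.77
THOC1	0.82
LSM8	0.83
PCBP1	0.87
RBM10	1.11
EIF4A3	1.12
CCDC130	1.12
RBM42	1.13
DGCR14	1.13
MFAP1	1.18
PUF60	1.18
THOC3	1.20
LSM6	1.21
RNF113A	1.24
FAM50B	1.25
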