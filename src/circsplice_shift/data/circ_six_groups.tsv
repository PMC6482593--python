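gene	db_id	reads_treated	reads_control	ratio	log2_ratio	mrna_fc	exon_count	group
SIPA1L3	hsa_circ_10577	9	2	4.5	2.17	1.12	2	up_up
PARD3B		4	1	4	2	1.19	12	up_up
CNTROB	hsa_circ_09218	4	1	4	2	1.11	1	up_up
FUT8	hsa_circ_02544	1	7	0.14	-2.81	1.2	1	down_up
RELL1	hsa_circ_08846	2	15	0.13	-2.91	1.15	3	down_up
SDF4	hsa_circ_21644	1	9	0.11	-3.17	1.15	2	down_up
FNDC3B	hsa_circ_15231	1	15	0.07	-3.91	1.13	2	down_up
TEX2	hsa_circ_31354	15	1	15	3.91	0.98	3	up_unchanged
PVT1	hsa_circ_16350	8	1	8	3		1	up_unchanged
CRIM1	hsa_circ_16396	15	2	7.5	2.91	1.03	3	up_unchanged
DOCK1	hsa_circ_00689	7	1	7	2.81	1.05	22	up_unchanged
HNRNPM	hsa_circ_20744	7	1	7	2.81	1.01	4	up_unchanged
SCAP	hsa_circ_19380	7	1	7	2.81	0.94	5	up_unchanged
VAMP3	hsa_circ_18051	7	1	7	2.81	0.94	2	up_unchanged
RP11-146B14.1		6	1	6	2.58		4	up_unchanged
GRHPR	hsa_circ_03935	6	1	6	2.58	1.06	3	up_unchanged
FOXP1	hsa_circ_19469	6	1	6	2.58	1.01	5	up_unchanged
SMURF2	hsa_circ_01208	5	1	5	2.32	1.11	5	up_unchanged
L3MBTL3		5	1	5	2.32	1.03	18	up_unchanged
RUNX1T1		5	1	5	2.32	0.99	4	up_unchanged
KANSL1L	hsa_circ_06859	5	1	5	2.32	0.96	3	up_unchanged
TBC1D8	hsa_circ_32540	5	1	5	2.32	0.94	6	up_unchanged
LZIC	hsa_circ_31394	5	1	5	2.32	0.94	3	up_unchanged
TTC28	hsa_circ_22261	5	1	5	2.32	0.93	2	up_unchanged
CSNK1G3	hsa_circ_08140	14	3	4.67	2.22	0.93	3	up_unchanged
TPST1	hsa_circ_22617	9	2	4.5	2.17	0.98	2	up_unchanged
PRKY	hsa_circ_30664	4	1	4	2		4	up_unchanged
PCNXL2	hsa_circ_10712	4	1	4	2		2	up_unchanged
CUX1	hsa_circ_12403	8	2	4	2	1.11	1	up_unchanged
PPP6R2	hsa_circ_07544	4	1	4	2	1.11	2	up_unchanged
DNAAF5		4	1	4	2	1.1	3	up_unchanged
FAM213A		4	1	4	2	1.06	3	up_unchanged
EVI5	hsa_circ_11187	4	1	4	2	1.04	3	up_unchanged
FIP1L1	hsa_circ_18069	4	1	4	2	1.02	3	up_unchanged
ECSIT	hsa_circ_00599	4	1	4	2	1	2	up_unchanged
XXYLT1	hsa_circ_02143	4	1	4	2	1	2	up_unchanged
ATXN1	hsa_circ_13397	4	1	4	2	0.99	1	up_unchanged
CDK8	hsa_circ_27078	4	1	4	2	0.98	3	up_unchanged
RYK	hsa_circ_26048	4	1	4	2	0.98	7	up_unchanged
ACVR2A	hsa_circ_04751	4	1	4	2	0.98	3	up_unchanged
SCAF8	hsa_circ_06913	4	1	4	2	0.98	5	up_unchanged
BABAM1	hsa_circ_04303	4	1	4	2	0.96	2	up_unchanged
PDS5A	hsa_circ_29001	4	1	4	2	0.95	5	up_unchanged
VRK1	hsa_circ_08594	4	1	4	2	0.94	10	up_unchanged
IQGAP1	hsa_circ_10932	4	1	4	2	0.93	4	up_unchanged
PSD3	hsa_circ_02851	1	7	0.14	-2.81	1.05	4	down_unchanged
UBAP2	hsa_circ_30156	1	7	0.14	-2.81	0.94	4	down_unchanged
N4BP2L2	hsa_circ_12240	1	7	0.14	-2.81	0.93	4	down_unchanged
TBCD	hsa_circ_00754	2	15	0.13	-2.91	1.05	6	down_unchanged
PTK2	hsa_circ_23485	2	15	0.13	-2.91	1.03	3	down_unchanged
CORO1C	hsa_circ_01619	1	9	0.11	-3.17	1.06	2	down_unchanged
RARS	hsa_circ_21209	1	9	0.11	-3.17	1.01	4	down_unchanged
ADAMTS6	hsa_circ_28538	3	29	0.1	-3.27	1.05	6	down_unchanged
SCMH1	hsa_circ_12377	1	10	0.1	-3.32	1.09	2	down_unchanged
FAM13B	hsa_circ_11413	1	10	0.1	-3.32	1.01	3	down_unchanged
EPHB4	hsa_circ_08510	1	10	0.1	-3.32	1	2	down_unchanged
ASPH	hsa_circ_10828	1	11	0.09	-3.46	1	2	down_unchanged
ESYT2	hsa_circ_25060	1	11	0.09	-3.46	0.95	5	down_unchanged
MAN1A2	hsa_circ_02643	1	15	0.07	-3.91	1.06	4	down_unchanged
ASAP1	hsa_circ_09642	1	15	0.07	-3.91	0.93	6	down_unchanged
MYO9A		8	1	8	3	0.75	12	up_down
ARFGEF2		5	1	5	2.32	0.91	3	up_down
RNF138	hsa_circ_01057	5	1	5	2.32	0.9	2	up_down
RNF38	hsa_circ_32756	5	1	5	2.32	0.79	2	up_down
PDS5B	hsa_circ_01546	4	1	4	2	0.91	2	up_down
SLF2		4	1	4	2	0.9	2	up_down
NEIL3	hsa_circ_00262	4	1	4	2	0.84	2	up_down
UGGT1		4	1	4	2	0.78	15	up_down
MACF1		4	1	4	2	0.68	11	up_down
RCAN3	hsa_circ_22201	4	1	4	2	0.67	1	up_down
BMPR2	hsa_circ_06837	1	7	0.14	-2.81	0.84	2	down_down
ANKRD12	hsa_circ_31497	1	7	0.14	-2.81	0.78	6	down_down
NFAT5	hsa_circ_16704	1	8	0.13	-3	0.64	1	down_down
ANKRD17	hsa_circ_01636	1	9	0.11	-3.17	0.91	1	down_down
CEP192	hsa_circ_26363	1	9	0.11	-3.17	0.85	8	down_down
FGD4	hsa_circ_21030	1	9	0.11	-3.17	0.85	6	down_down
RHOBTB3	hsa_circ_19124	1	17	0.06	-4.09	0.91	2	down_down
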