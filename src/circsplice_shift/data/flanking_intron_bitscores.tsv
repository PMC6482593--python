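gene	db_id	pident	bitscore	group
PARD3B		98.44	4617	up_up
SIPA1L3	hsa_circ_10577	90.24	374	up_up
FUT8	hsa_circ_02544	93.17	429	down_up
RELL1	hsa_circ_08846	88.03	335	down_up
FNDC3B	hsa_circ_15231	84.59	311	down_up
PCNXL2	hsa_circ_10712	98.65	525	up_unchanged
RUNX1T1	hsa_circ_02162	89.74	427	up_unchanged
DOCK1	hsa_circ_00689	89.61	387	up_unchanged
TTC28	hsa_circ_22261	89.6	375	up_unchanged
ATXN1	hsa_circ_13397	89.45	300	up_unchanged
XXYLT1	hsa_circ_02143	89.26	521	up_unchanged
ECSIT	hsa_circ_00599	88.63	361	up_unchanged
CUX1	hsa_circ_12403	87.25	333	up_unchanged
EVI5	hsa_circ_11187	86.53	363	up_unchanged
SMURF2	hsa_circ_01208	86.23	324	up_unchanged
IQGAP1	hsa_circ_10932	86.13	291	up_unchanged
TEX2	hsa_circ_31354	85.26	316	up_unchanged
TBC1D8	hsa_circ_32540	84.04	263	up_unchanged
TPST1	hsa_circ_22617	83.83	560	up_unchanged
LZIC	hsa_circ_31394	83.55	278	up_unchanged
SCAF8	hsa_circ_06913	83.05	261	up_unchanged
KANSL1L	hsa_circ_06859	82.95	191	up_unchanged
VRK1	hsa_circ_08594	82.95	115	up_unchanged
DNAAF5		82.87	254	up_unchanged
PDS5A	hsa_circ_29001	82.68	257	up_unchanged
PPP6R2	hsa_circ_07544	82.34	499	up_unchanged
ACVR2A	hsa_circ_04751	81.88	255	up_unchanged
VAMP3	hsa_circ_18051	81.76	250	up_unchanged
PRKY	hsa_circ_30664	81.66	230	up_unchanged
CSNK1G3	hsa_circ_08140	80.89	226	up_unchanged
PVT1	hsa_circ_16350	76.23	619	up_unchanged
FAM13B	hsa_circ_11413	89.9	379	down_unchanged
SCMH1	hsa_circ_12377	89.74	387	down_unchanged
N4BP2L2	hsa_circ_12240	88.45	363	down_unchanged
ADAMTS6	hsa_circ_28538	88.41	353	down_unchanged
PSD3	hsa_circ_02851	87.66	351	down_unchanged
UBAP2	hsa_circ_30156	87.63	326	down_unchanged
PTK2	hsa_circ_23485	85.49	396	down_unchanged
ASAP1	hsa_circ_09642	84.95	294	down_unchanged
MAN1A2	hsa_circ_02643	84.03	272	down_unchanged
EPHB4	hsa_circ_08510	82.08	257	down_unchanged
UGGT1		87.2	326	up_down
RNF38	hsa_circ_32756	86.81	318	up_down
RNF138	hsa_circ_01057	86.3	315	up_down
SLF2		85.76	315	up_down
RCAN3	hsa_circ_22201	83.84	278	up_down
PDS5B	hsa_circ_01546	82.06	254	up_down
RHOBTB3	hsa_circ_19124	90.64	392	down_down
ANKRD12	hsa_circ_31497	85.86	313	down_down
ANKRD17	hsa_circ_01636	85.37	296	down_down
CEP192	hsa_circ_26363	84.76	307	down_down
BMPR2	hsa_circ_06837	81.99	503	down_down
FGD4	hsa_circ_21030	78.65	115	down_down
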