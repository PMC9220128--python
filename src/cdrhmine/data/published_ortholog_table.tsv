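group	gene	domain	same	different	non_rga	total
Brassica	Bju_WRR1	CNL	14 CNL	12 NL, 3 CN, 1 Other-RLK	16	46
Brassica	Bna_MAPk	Other-RLK	1 Other-RLK		31	32
Brassica	Bra_cRa/cRb	TNL	9 TNL	4 Other-NLR, 12 TN, 1 Other-RLK, 3 TX	1	19
Brassica	Bra_Crr1a	TNL	9 TNL	1 NL, 1 Other-NLR, 1 CNL, 2 TX	8	22
Brassica	Bol_FocBo1	TNL	7 TNL	1 Other-NLR, 1 TN, 1 TX	5	15
Brassica	Bna_LepR3/Rlm2	LRR-RLP	4 LRR-RLP		3	7
Brassica	Bna_Rlm9/4/7	Other-RLK	56 Other-RLK		28	84
Brassica	TOTAL		100	94	94	229
At	At_ADR1	NL	2 NL	3 CNL	0	5
At	At_BAK1	LRR-RLK	30 LRR-RLK		11	41
At	At_FLS2	LRR-RLK	13 LRR-RLK	1 LRR-RLP	5	19
At	At_NDR1	TM			22	22
At	At_NRG1a	RNL		6 CNL, 1 LRR-RLP, 1 NBS, 17 NL	4	29
At	At_NRG1b	RNL		8 CNL, 1 LRR-RLP, 1 NBS, 16 NL	4	29
At	At_PBS1	STK		1 NL	36	37
At	At_RAC1	TNL		1 NBS	0	1
At	At_RFO1	Other-RLK	2 Other-RLK		1	3
At	At_RFO2	LRR-RLP	4 LRR-RLP		3	7
At	At_RFO3	Other-RLK	15 Other-RLK	1 Other-NLR	6	22
At	At_RIN4	CC			0	0
At	At_RLM1a	TNL			0	0
At	At_RLM1b	TNL	9 TNL	3 NL, 1 Other-NLR, 2 TN, 1 TX	6	22
At	At_RLM3	TN			0	0
At	At_RPM1	NL	4 NL	1 NBS	5	10
At	At_RLP1	LRR-RLP	7 LRR-RLP		4	11
At	At_RLP23	LRR-RLP			2	2
At	At_RLP30	LRR-RLP			0	0
At	At_RLP32	LRR-RLP	4 LRR-RLP		2	6
At	At_RLP42	LRR-RLP			2	2
At	At_RPP1	TNL			0	0
At	At_RPP2a	TNL	6 TNL	1 NBS	2	9
At	At_RPP2b	TNL	6 TNL	1 NBS	4	11
At	At_RPP4	TNL			0	0
At	At_RPP5	TNL	1 TNL		0	1
At	At_RPP5	NL			0	0
At	At_RPP8	CNL		4 NL, 1 CN	0	5
At	At_RPP13	CNL	1 CNL	2 CN, 2 NBS, 1 NL	3	9
At	At_RPP39	CNL	1 CNL	1 CN	0	2
At	At_RPS2	NL	2 NL	7 CNL, 1 LRR-RLK	1	11
At	At_RPS4	TNL	6 TNL	1 NL, 1 TN, 1 LRR-RLP	2	11
At	At_RPS5	TNL			0	0
At	At_Rpw8.1	RNL			0	0
At	At_Rpw8.2	RNL			0	0
At	At_RRS1	TNL	1 TNL	2 NL	0	3
At	At_SOBIR1	LRR-RLK	21 LRR-RLK	2 LRR-RLP	2	23
At	At_WRR4a	TNL			0	0
At	At_WRR4b	TNL			0	0
At	At_WRR8	TNL		1 NL, 1 NBS	0	2
At	At_WRR9	NL			0	0
At	At_WRR12	TNL	7 TNL	5 Other-NLR, 3 NBS, 3 NL, 1 TN, 3 TX, 1 LRR-RLP	1	24
At	TOTAL		144	61	120	323
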