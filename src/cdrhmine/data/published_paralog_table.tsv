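group	gene	domain	tandem	segmented	same	different	non_rga	total
Brassica	Bju_WRR1	CNL	0	1		1 TX	0	1
Brassica	Bna_MAPk	Other-RLK	0	8			8	8
Brassica	Bra_cRa/cRb	TNL	3	1	1 TNL	1 NL, 2 TX	0	4
Brassica	Bra_Crr1a	TNL	1	2	1 TNL	2 TX	1	3
Brassica	Bol_FocBo1	TNL	0	0			0	0
Brassica	Bna_LepR3/Rlm2	LRR-RLP	0	1	1 LRR-RLP		0	1
Brassica	Bna_Rlm9/4/7	Other-RLK	0	6	3 Other-RLK		3	6
Brassica	TOTAL		4	19	6	6	14	23
At	At_ADR1	NL	0	2	2 NL		0	2
At	At_BAK1	LRR-RLK	0	4	4 LRR-RLK		0	4
At	At_FLS2	LRR-RLK	0	0			0	0
At	At_NDR1	TM	1	0			1	1
At	At_NRG1a	RNL	1	0		1 NL	0	1
At	At_NRG1b	RNL	1	0		1 NL	0	1
At	At_PBS1	STK	0	0			0	0
At	At_RAC1	TNL	0	4	3 TNL	1 TN	0	4
At	At_RFO1	Other-RLK	0	0			0	0
At	At_RFO2	LRR-RLP	0	1		1 LRR-RLK	0	1
At	At_RFO3	Other-RLK	0	1	1 Other-RLK		0	1
At	At_RIN4	CC	0	0			0	0
At	At_RLM1a	TNL	0	0			0	0
At	At_RLM1b	TNL	5	2	6 TNL	1 NL	0	7
At	At_RLM3	TN	0	0			0	0
At	At_RPM1	NL	0	0			0	0
At	At_RLP1	LRR-RLP	0	0			0	0
At	At_RLP23	LRR-RLP	3	0	3 LRR-RLP		0	3
At	At_RLP30	LRR-RLP	0	0			0	0
At	At_RLP32	LRR-RLP	0	1	1 LRR-RLP		0	1
At	At_RLP42	LRR-RLP	3	0	3 LRR-RLP		0	3
At	At_RPP1	TNL	3	3	5 TNL	1 TX	0	6
At	At_RPP2a	TNL	0	0			0	0
At	At_RPP2b	TNL	0	0			0	0
At	At_RPP4	TNL	6	0	5 TNL	1 Other-NLR	0	6
At	At_RPP5	TNL	7	0	5 TNL	1 Other-NLR	1	7
At	At_RPP5	NL	4	0		4 CNL	0	4
At	At_RPP8	CNL	2	0	2 CNL		0	2
At	At_RPP13	CNL	0	0			0	0
At	At_RPP39	CNL	3	0	2 CNL	1 NL	0	3
At	At_RPS2	NL	0	0			0	0
At	At_RPS4	TNL	1	0	1 TNL		0	1
At	At_RPS5	TNL	0	0			0	0
At	At_Rpw8.1	RNL	0	0			0	0
At	At_Rpw8.2	RNL	0	0			0	0
At	At_RRS1	TNL	1	0		1 NL	0	1
At	At_SOBIR1	LRR-RLK	0	0			0	0
At	At_WRR4a	TNL	1	0	1 TNL		0	1
At	At_WRR4b	TNL	0	0			0	0
At	At_WRR8	TNL	3	1	3 TNL	1 TN	0	4
At	At_WRR9	NL	0	1			1	1
At	At_WRR12	TNL	0	1	1 TNL		0	1
At	TOTAL		43	22	49	13	3	65
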