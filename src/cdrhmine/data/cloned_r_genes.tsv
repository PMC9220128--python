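gene_id	aliases	species_code	rga_type	pathogens	diseases	accession	length_aa	protein_seq	chrom	start	end	strand
At_ADR1		At	RNL	Hyaloperonospora arabidopsidis;Erysiphe cichoracearum;Pseudomonas syringae	BLS;DM;PW	Q9FW44	300
At_BAK1		At	LRR-RLK	Pseudomonas syringae;Sclerotinia sclerotiorum	BLS;SSR	Q94F62	380
At_FLS2		At	LRR-RLK	Pseudomonas syringae	BLS	Q9FL28	380
At_NDR1		At	TM	Pseudomonas syringae	BLS	O48915	219
At_NRG1a	At_NGR1a	At	RNL	Albugo candida;Hyaloperonospora arabidopsidis;Pseudomonas syringae	BLS;DM	Q9FKZ1	300
At_NRG1b	At_NGR1b	At	RNL	Albugo candida;Hyaloperonospora arabidopsidis;Pseudomonas syringae	BLS;DM	Q9FKZ0	300
At_PBS1		At	STK	Pseudomonas syringae	BLS	Q9FE20	260
At_RAC1		At	TNL	Albugo candida	WR	Q6QX58	360
At_RIN4		At	CC	Pseudomonas syringae	BLS	Q8GYN5	211
At_RFO1		At	Other-RLK	Fusarium oxysporum matthioli	FW	Q8RY17	300
At_RFO2		At	LRR-RLP	Fusarium oxysporum matthioli	FW	Q9SHI4	350
At_RFO3		At	Other-RLK	Fusarium oxysporum matthioli	FW	Q9LW83	300
At_RLM1a		At	TNL	Leptosphaeria maculans	BL	Q9CAK1	360
At_RLM1b		At	TNL	Leptosphaeria maculans	BL	F4I594	360
At_RLM3		At	TN	Leptosphaeria maculans;Botrytis cinerea;Alternaria brassicicola;Alternaria brassicae	BL;GM	Q9FT77	260
At_RLP1		At	LRR-RLP	Xanthomonas spp.	BR	Q9LNV9	350
At_RLP23		At	LRR-RLP	Sclerotinia sclerotiorum	SSR	O48849	350
At_RLP30		At	LRR-RLP	Pseudomonas syringae;Sclerotinia sclerotiorum	BLS;SSR	Q9MA83	350
At_RLP32		At	LRR-RLP	Pseudomonas syringae	BLS	Q9M9X0	350
At_RLP42		At	LRR-RLP	Botrytis cinerea;Hyaloperonospora arabidopsidis	DM;GM	Q9LJS0	350
At_RPM1		At	NL	Pseudomonas syringae	BLS	Q39214	320
At_RPP1		At	TNL	Hyaloperonospora arabidopsidis	DM	F4J339	360
At_RPP2a		At	TNL	Hyaloperonospora arabidopsidis	DM	F4JT78	360
At_RPP2b		At	TNL	Hyaloperonospora arabidopsidis	DM	F4JT80	360
At_RPP4		At	TNL	Hyaloperonospora arabidopsidis	DM	F4JNA9	360
At_RPP5		At	TNL	Hyaloperonospora arabidopsidis	DM	F4JNB7	360
At_RPP7		At	NL	Hyaloperonospora arabidopsidis	DM	Q8W3K0	320
At_RPP8		At	CNL	Hyaloperonospora arabidopsidis	DM	Q8W4J9	340
At_RPP13		At	CNL	Hyaloperonospora arabidopsidis	DM	Q9M667	340
At_RPP39		At	CNL	Hyaloperonospora arabidopsidis	DM	H9BPR9	340
At_RPS2		At	NL	Pseudomonas syringae	BLS	Q42484	320
At_RPS4		At	TNL	Pseudomonas syringae	BLS	Q9XGM3	360
At_RPS5		At	TNL	Pseudomonas syringae	BLS	O64973	360
At_Rpw8.1	At_RPW8.1	At	RNL	Erysiphe cichoracearum	PW	Q9C5Z7	148
At_Rpw8.2	At_RPW8.2	At	RNL	Erysiphe cichoracearum	PW	Q9C5Z6	174
At_RRS1		At	TNL	Pseudomonas syringae;Ralstonia solanacearum;Colletotrichum higginsianum	BLS	P0DKH5	360
At_SOBIR1		At	LRR-RLK	Pseudomonas syringae;Sclerotinia sclerotiorum	BLS;SSR	Q9SKB2	380
At_WRR4a		At	TNL	Albugo candida	WR	Q9C7X0	360
At_WRR4b		At	TNL	Albugo candida	WR	MK034466	360
At_WRR8		At	TNL	Albugo candida	WR	MK034463	360
At_WRR9		At	NL	Albugo candida	WR	MK034464	320
At_WRR12		At	TNL	Albugo candida	WR	MK034462	360
Bju_WRR1		Bju	CNL	Albugo candida	WR	A0A5C1IWT6	340
Bna_MAPk	Bna_MPK9	Bna	Other-RLK	Leptosphaeria maculans	BL	A0A078IFE9	300
Bna_LepR3/Rlm2		Bna	LRR-RLP	Leptosphaeria maculans	BL	I7C3X3;A0A0B5L618	350
Bna_Rlm9/4/7		Bna	Other-RLK	Leptosphaeria maculans	BL	CDX67982.1	300
Bra_cRa/cRb		Bra	TNL	Plasmodiophora brassicae	CR	M5A8J3	360
Bra_Crr1a		Bra	TNL	Plasmodiophora brassicae	CR	AB605024.1	360
Bol_FocBo1		Bol	TNL	Fusarium oxysporum conglutinans	FW	BAQ21734.1	360
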