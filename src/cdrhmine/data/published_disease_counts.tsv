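disease	cdrh_count	rga_count	non_rga_count
BLS	239	153	86
BR		6
BL	165	86	79
WR	123	102	21
DM	109	95	14
CR	48	38
SSR	75	60
FW	50	34	16
PW	9	9
GM	5	3	2
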