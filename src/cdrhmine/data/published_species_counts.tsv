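species_code	cdrh_count	cluster_count
Bju	136	11
Bca	119	14
Bna	101	13
Bra	80	9
Bol	78	7
Bni	78	12
At	68	21
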