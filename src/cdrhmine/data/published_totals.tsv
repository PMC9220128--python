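key	value
total_cdrhs	660
total_rgas	431
total_non_rgas	229
nlr_total	248
rlk_total	150
rlp_total	33
homogeneous_clusters	55
heterogeneous_clusters	32
total_clusters	87
homog_nlr_clusters	36
homog_rlk_clusters	16
homog_rlp_clusters	3
at_paralog_total_text	62
at_tandem_text	43
at_segmented_text	18
brassica_paralog_total_text	23
brassica_segmented_text	19
brassica_tandem_text	4
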