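bin_id	cds_over_7x	cds_no_snps	cds_multi_variant	winter_only	summer_only	both_seasons
FlavA	43	24	13	1	22	4
FlavG	24	5	15	4	12	20
FlavH	11	1	9	5	2	14
FlavI	11	3	7	13	0	4
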