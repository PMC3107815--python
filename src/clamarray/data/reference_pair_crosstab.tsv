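tissue	f_class	r_lt_1p5	r_1p5_3	r_3_10	r_ge_10
gills	f_lt_10	1683	1197	1319	4920
gills	f_10_100	194	296	592	2872
gills	f_100_1000	66	119	162	707
gills	f_ge_1000	15	23	45	130
digestive_gland	f_lt_10	1783	1451	1936	5530
digestive_gland	f_10_100	227	358	583	2174
digestive_gland	f_100_1000	45	84	105	583
digestive_gland	f_ge_1000	6	16	22	124
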