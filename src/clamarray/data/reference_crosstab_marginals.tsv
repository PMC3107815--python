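tissue	r_lt_1p5	r_1p5_3	r_3_10	r_ge_10	grand_total
gills	1958	1635	2118	8629	14340
digestive_gland	2061	1909	2646	8411	15027
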