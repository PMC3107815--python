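q_threshold	n_discordant	n_concordant_up_digestive_gland	n_concordant_up_gills
0.18	898	532	3489
0.10	176	195	2671
0.011	30	97	561
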