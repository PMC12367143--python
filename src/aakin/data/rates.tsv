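enzyme	step_id	k_forward	k_backward	units
cysRS	aa_bind	5.0	569.8526332742791	uM-1.s-1
cysRS	atp_bind	0.1	118.33760129659696	uM-1.s-1
cysRS	atp_bind_a	0.1	118.33760129659696	uM-1.s-1
cysRS	aa_bind_t	5.0	569.8526332742791	uM-1.s-1
cysRS	act	445.55299999999994	222.77649999999997	s-1
cysRS	ppi_rel	300.0	0.15	s-1
cysRS	trna_bind_0	0.8705948154595752	0.5	uM-1.s-1
cysRS	trna_bind_a	0.8705948154595752	0.5	uM-1.s-1
cysRS	trna_bind_t	0.8705948154595752	0.5	uM-1.s-1
cysRS	trna_bind_at	0.8705948154595752	0.5	uM-1.s-1
cysRS	trna_bind_d	2.862685417327721	0.5	uM-1.s-1
cysRS	aa_bind_r	31.188129559639876	20731.50667329772	uM-1.s-1
cysRS	atp_bind_r	0.2	200.0	uM-1.s-1
cysRS	atp_bind_ra	0.2	200.0	uM-1.s-1
cysRS	aa_bind_rt	31.188129559639876	94352.74342776295	uM-1.s-1
cysRS	act_r	445.55299999999994	222.77649999999997	s-1
cysRS	ppi_rel_r	1000.0	0.15	s-1
cysRS	tran	16.99234008534556	0.5	s-1
cysRS	tran_p	16.99234008534556	0.5	s-1
cysRS	ppi_rel_q	1000.0	0.15	s-1
cysRS	amp_rel	382.2250527379054	0.05	s-1
cysRS	atp_bind_p	0.1	100.0	uM-1.s-1
cysRS	prod_rel_t	3.3386157920344397	0.01	s-1
cysRS	prod_rel	4.019404284782769	0.01	s-1
hisRS	aa_bind	5.0	713.093946642893	uM-1.s-1
hisRS	atp_bind	0.1	205.33245026119977	uM-1.s-1
hisRS	atp_bind_a	0.1	205.33245026119977	uM-1.s-1
hisRS	aa_bind_t	5.0	713.093946642893	uM-1.s-1
hisRS	act	702.1645572942956	351.0822786471478	s-1
hisRS	ppi_rel	300.0	0.15	s-1
hisRS	trna_bind_0	5.019207130326532	0.5	uM-1.s-1
hisRS	trna_bind_a	5.019207130326532	0.5	uM-1.s-1
hisRS	trna_bind_t	5.019207130326532	0.5	uM-1.s-1
hisRS	trna_bind_at	5.019207130326532	0.5	uM-1.s-1
hisRS	trna_bind_d	17.251018362434504	0.5	uM-1.s-1
hisRS	aa_bind_r	5.0	35818.47507100741	uM-1.s-1
hisRS	atp_bind_r	0.2	200.0	uM-1.s-1
hisRS	atp_bind_ra	0.2	200.0	uM-1.s-1
hisRS	aa_bind_rt	5.0	129704.98410473956	uM-1.s-1
hisRS	act_r	702.1645572942956	351.0822786471478	s-1
hisRS	ppi_rel_r	1000.0	0.15	s-1
hisRS	tran	22.27168300768174	0.5	s-1
hisRS	tran_p	22.27168300768174	0.5	s-1
hisRS	ppi_rel_q	1000.0	0.15	s-1
hisRS	amp_rel	659.9841496949813	0.05	s-1
hisRS	aa_bind_2	5.0	500.0	uM-1.s-1
hisRS	atp_bind_2	0.1	100.0	uM-1.s-1
hisRS	atp_bind_2a	0.1	100.0	uM-1.s-1
hisRS	aa_bind_2t	5.0	500.0	uM-1.s-1
hisRS	act_2	702.1645572942956	351.0822786471478	s-1
hisRS	ppi_rel_2	1000.0	0.15	s-1
hisRS	prod_rel_dp	38.41808996573442	0.01	s-1
hisRS	prod_rel_d	11.303533481486987	0.01	s-1
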