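trait	label	n	mean	sd
culm_length_cm	DH120366	25	84.06	2.91
culm_length_cm	nud_8-3	20	85.03	4.16
culm_length_cm	nud_8-10	40	84.18	5.15
thousand_grain_weight_g	DH120366	5	35.56	3.00
thousand_grain_weight_g	nud_8-3	4	34.20	3.02
thousand_grain_weight_g	nud_8-10	8	33.05	2.47
hectoliter_weight_kg_hl	DH120366	5	64.60	2.66
hectoliter_weight_kg_hl	nud_8-3	4	80.01	1.71
hectoliter_weight_kg_hl	nud_8-10	4	76.85	1.28
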