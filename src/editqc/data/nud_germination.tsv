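trait	label	n	mean	sd
germination_rate_trial1	DH120366	4	0.86	0.04
germination_rate_trial1	nud_8-3	4	0.79	0.07
germination_rate_trial1	nud_8-10	4	0.82	0.12
germination_rate_trial2	DH120366	4	0.90	0.04
germination_rate_trial2	nud_8-3	4	0.88	0.15
germination_rate_trial2	nud_8-10	4	0.98	0.04
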