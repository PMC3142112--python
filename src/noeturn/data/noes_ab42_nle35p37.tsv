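# NOESY crosspeaks reported for the full-length mutant (Abeta42 Nle35 p37):
# intraresidue Ha-NH at G25, S26, G38, V39; sequential NH-NH V24-G25,
# G25-S26, G38-V39; sequential Ha-NH p37-G38; Ha-Hd V36-p37.
res_i	atom_i	res_j	atom_j	intensity_class
25	HA	25	HN	observed
26	HA	26	HN	observed
38	HA	38	HN	observed
39	HA	39	HN	observed
24	HN	25	HN	observed
25	HN	26	HN	observed
38	HN	39	HN	observed
37	HA	38	HN	observed
36	HA	37	HD	observed
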