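# NOESY crosspeaks reported for the truncated construct (Abeta21-43 Nle35 p37):
# intraresidue Ha-NH at G38, V39; sequential Ha-NH p37-G38; sequential NH-NH
# G38-V39; Ha-Hd V36-p37. No NH-NH crosspeaks around V24-N27.
res_i	atom_i	res_j	atom_j	intensity_class
38	HA	38	HN	observed
39	HA	39	HN	observed
37	HA	38	HN	observed
38	HN	39	HN	observed
36	HA	37	HD	observed
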