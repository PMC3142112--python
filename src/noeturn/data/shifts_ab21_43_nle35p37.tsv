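Amino acid	NH	αH	βH	others
E22	8.543	4.743	1.92	γH 1.268
D23	8.47	4.455	2.795
V24	8.275	4.17	1.873	γH 0.926
G25	8.418	3.788
S26	8.214	3.9	4.451
N27	8.644	4.661	2.682
K28	8.464	4.665	1.978,1.885	γH 1.423; εH 2.8
G29	8.616	3.993
A30	8.068	4.333	1.374
I31	8.179	4.172	1.874	γH 1.202; εH 0.889
I32	8.54	4.218	1.91	εH 0.93
G33	8.464	3.949
L34	8.141	4.428	1.642	δH 0.9494
NL35	8.242	4.675	1.606
V36	8.648	4.537	2.023	γH 0.957
dP37		4.423	2.373	γH 2.006 , 2.1; δH 3.892
G38	8.401	3.97
V39	7.853	4.274	2.88	γH 0.92
V40	8.446	4.487	1.98	γH 0.9118
I41	8.314	4.168	2.191	γH 0.9655
A42	8.442	4.178	1.418
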