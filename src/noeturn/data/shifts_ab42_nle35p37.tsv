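Amino acid	NH	αH	βH	Others
Y10	8.02	4.554	2.95, 3.08
K16	8.242	4.317	1.554, 1.662	δH 1,405
E22	8.18	4.355	2.218
D23	8.349	4.672	2.685
V24	8.379	4.292	1.806	γH 0.9618
G25	8.143	4.01
S26	8.203	3.927	4.484
N27	8.339	4.616	3.063
K28	8.475	3.97	-	εH 2.293
G29	8.64	3.898
A30	8.082	4.366	1.406
I31	8.165	4.196	1.909	εH 0.9618
I32	8.627	4.17	1.9	εH 0.9591
G33	8.602	4.026
L34	8.143	4.445	1.627	-
NL35	8.301	4.63	1.616	γH1.227, εH1.105
V36	8.7	4.583	2.021	γH 0.9852
dP37		4.22	2.39	γH 2.081, 2.143; δH 3.885
G38	8.494	3.791
V39	7.88	4.3	2.12	γH 0.94
V40	8.488	4.235	2.248	γH 0.9513
I41	8.678	4.291	2.016	εH 0.981
A42	7.989	4.36	1.401
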