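# Random-coil 1H chemical shifts (ppm), Wishart-style reference set
# (Ac-GGXAGG-NH2 peptide values). NLE uses Leu values (closest isostere);
# DPR uses Pro values (mirror image, identical shifts). Prolines have no NH.
residue	nucleus	shift_ppm
ALA	NH	8.24
ALA	HA	4.32
CYS	NH	8.32
CYS	HA	4.55
ASP	NH	8.34
ASP	HA	4.64
GLU	NH	8.42
GLU	HA	4.35
PHE	NH	8.30
PHE	HA	4.62
GLY	NH	8.33
GLY	HA	3.96
HIS	NH	8.42
HIS	HA	4.73
ILE	NH	8.00
ILE	HA	4.17
LYS	NH	8.29
LYS	HA	4.32
LEU	NH	8.16
LEU	HA	4.34
MET	NH	8.28
MET	HA	4.48
ASN	NH	8.40
ASN	HA	4.74
PRO	HA	4.42
GLN	NH	8.32
GLN	HA	4.34
ARG	NH	8.23
ARG	HA	4.34
SER	NH	8.31
SER	HA	4.47
THR	NH	8.15
THR	HA	4.35
VAL	NH	8.03
VAL	HA	4.12
TRP	NH	8.25
TRP	HA	4.66
TYR	NH	8.12
TYR	HA	4.55
NLE	NH	8.16
NLE	HA	4.34
DPR	HA	4.42
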