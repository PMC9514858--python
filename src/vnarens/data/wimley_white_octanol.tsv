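res_name	delta_g_kcal_mol
ALA	0.50
ARG	1.81
ASN	0.85
ASP	3.64
CYS	-0.02
GLN	0.77
GLU	3.63
GLY	1.15
HIS	0.11
ILE	-1.12
LEU	-1.25
LYS	2.80
MET	-0.67
PHE	-1.71
PRO	0.14
SER	0.46
THR	0.25
TRP	-2.09
TYR	-0.71
VAL	-0.46
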