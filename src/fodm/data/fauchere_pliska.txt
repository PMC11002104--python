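# Fauchere-Pliska octanol/water partition scale (raw values; rescaled to [0,1] on load)
ALA 0.31
ARG -1.01
ASN -0.60
ASP -0.77
CYS 1.54
GLN -0.22
GLU -0.64
GLY 0.00
HIS 0.13
ILE 1.80
LEU 1.70
LYS -0.99
MET 1.23
PHE 1.79
PRO 0.72
SER -0.04
THR 0.26
TRP 2.25
TYR 0.96
VAL 1.22
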