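resname,propensity
ALA,0.7
ARG,1.0
ASN,0.9
ASP,0.6
CYS,1.2
GLN,0.9
GLU,0.5
GLY,0.8
HIS,1.5
ILE,1.3
LEU,1.2
LYS,0.6
MET,1.5
PHE,1.8
PRO,0.4
SER,0.7
THR,0.8
TRP,2.3
TYR,1.6
VAL,1.0
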