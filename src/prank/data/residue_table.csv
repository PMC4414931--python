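resname,hydropathy,aliphatic,aromatic,polar,charged_pos,charged_neg
ALA,1.8,1,0,0,0,0
ARG,-4.5,0,0,0,1,0
ASN,-3.5,0,0,1,0,0
ASP,-3.5,0,0,1,0,1
CYS,2.5,0,0,1,0,0
GLN,-3.5,0,0,1,0,0
GLU,-3.5,0,0,1,0,1
GLY,-0.4,1,0,0,0,0
HIS,-3.2,0,1,1,1,0
ILE,4.5,1,0,0,0,0
LEU,3.8,1,0,0,0,0
LYS,-3.9,0,0,0,1,0
MET,1.9,1,0,0,0,0
PHE,2.8,0,1,0,0,0
PRO,-1.6,1,0,0,0,0
SER,-0.8,0,0,1,0,0
THR,-0.7,0,0,1,0,0
TRP,-0.9,0,1,0,0,0
TYR,-1.3,0,1,1,0,0
VAL,4.2,1,0,0,0,0
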