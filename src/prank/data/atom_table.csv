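resname,atom,pharmacophore,propensity
ALA,N,donor,1.1
ALA,CA,none,0.5
ALA,C,none,0.5
ALA,O,acceptor,1.1
ALA,OXT,acceptor,1.1
ALA,CB,hydrophobic,0.7
ARG,N,donor,1.1
ARG,CA,none,0.5
ARG,C,none,0.5
ARG,O,acceptor,1.1
ARG,OXT,acceptor,1.1
ARG,CB,hydrophobic,0.7
ARG,CG,hydrophobic,0.7
ARG,CD,none,0.5
ARG,NE,donor,1.1
ARG,CZ,positive,0.9
ARG,NH1,positive,0.9
ARG,NH2,positive,0.9
ASN,N,donor,1.1
ASN,CA,none,0.5
ASN,C,none,0.5
ASN,O,acceptor,1.1
ASN,OXT,acceptor,1.1
ASN,CB,hydrophobic,0.7
ASN,CG,none,0.5
ASN,OD1,acceptor,1.1
ASN,ND2,donor,1.1
ASP,N,donor,1.1
ASP,CA,none,0.5
ASP,C,none,0.5
ASP,O,acceptor,1.1
ASP,OXT,acceptor,1.1
ASP,CB,hydrophobic,0.7
ASP,CG,none,0.5
ASP,OD1,negative,1.0
ASP,OD2,negative,1.0
CYS,N,donor,1.1
CYS,CA,none,0.5
CYS,C,none,0.5
CYS,O,acceptor,1.1
CYS,OXT,acceptor,1.1
CYS,CB,hydrophobic,0.7
CYS,SG,donor_acceptor,1.4
GLN,N,donor,1.1
GLN,CA,none,0.5
GLN,C,none,0.5
GLN,O,acceptor,1.1
GLN,OXT,acceptor,1.1
GLN,CB,hydrophobic,0.7
GLN,CG,hydrophobic,0.7
GLN,CD,none,0.5
GLN,OE1,acceptor,1.1
GLN,NE2,donor,1.1
GLU,N,donor,1.1
GLU,CA,none,0.5
GLU,C,none,0.5
GLU,O,acceptor,1.1
GLU,OXT,acceptor,1.1
GLU,CB,hydrophobic,0.7
GLU,CG,hydrophobic,0.7
GLU,CD,none,0.5
GLU,OE1,negative,1.0
GLU,OE2,negative,1.0
GLY,N,donor,1.1
GLY,CA,none,0.5
GLY,C,none,0.5
GLY,O,acceptor,1.1
GLY,OXT,acceptor,1.1
HIS,N,donor,1.1
HIS,CA,none,0.5
HIS,C,none,0.5
HIS,O,acceptor,1.1
HIS,OXT,acceptor,1.1
HIS,CB,hydrophobic,0.7
HIS,CG,aromatic,1.3
HIS,ND1,donor_acceptor,1.4
HIS,CD2,aromatic,1.3
HIS,CE1,aromatic,1.3
HIS,NE2,donor_acceptor,1.4
ILE,N,donor,1.1
ILE,CA,none,0.5
ILE,C,none,0.5
ILE,O,acceptor,1.1
ILE,OXT,acceptor,1.1
ILE,CB,hydrophobic,0.7
ILE,CG1,hydrophobic,0.7
ILE,CG2,hydrophobic,0.7
ILE,CD1,hydrophobic,0.7
LEU,N,donor,1.1
LEU,CA,none,0.5
LEU,C,none,0.5
LEU,O,acceptor,1.1
LEU,OXT,acceptor,1.1
LEU,CB,hydrophobic,0.7
LEU,CG,hydrophobic,0.7
LEU,CD1,hydrophobic,0.7
LEU,CD2,hydrophobic,0.7
LYS,N,donor,1.1
LYS,CA,none,0.5
LYS,C,none,0.5
LYS,O,acceptor,1.1
LYS,OXT,acceptor,1.1
LYS,CB,hydrophobic,0.7
LYS,CG,hydrophobic,0.7
LYS,CD,hydrophobic,0.7
LYS,CE,none,0.5
LYS,NZ,positive,0.9
MET,N,donor,1.1
MET,CA,none,0.5
MET,C,none,0.5
MET,O,acceptor,1.1
MET,OXT,acceptor,1.1
MET,CB,hydrophobic,0.7
MET,CG,hydrophobic,0.7
MET,SD,hydrophobic,0.7
MET,CE,hydrophobic,0.7
PHE,N,donor,1.1
PHE,CA,none,0.5
PHE,C,none,0.5
PHE,O,acceptor,1.1
PHE,OXT,acceptor,1.1
PHE,CB,hydrophobic,0.7
PHE,CG,aromatic,1.3
PHE,CD1,aromatic,1.3
PHE,CD2,aromatic,1.3
PHE,CE1,aromatic,1.3
PHE,CE2,aromatic,1.3
PHE,CZ,aromatic,1.3
PRO,N,none,0.5
PRO,CA,none,0.5
PRO,C,none,0.5
PRO,O,acceptor,1.1
PRO,OXT,acceptor,1.1
PRO,CB,hydrophobic,0.7
PRO,CG,hydrophobic,0.7
PRO,CD,none,0.5
SER,N,donor,1.1
SER,CA,none,0.5
SER,C,none,0.5
SER,O,acceptor,1.1
SER,OXT,acceptor,1.1
SER,CB,hydrophobic,0.7
SER,OG,donor_acceptor,1.4
THR,N,donor,1.1
THR,CA,none,0.5
THR,C,none,0.5
THR,O,acceptor,1.1
THR,OXT,acceptor,1.1
THR,CB,hydrophobic,0.7
THR,OG1,donor_acceptor,1.4
THR,CG2,hydrophobic,0.7
TRP,N,donor,1.1
TRP,CA,none,0.5
TRP,C,none,0.5
TRP,O,acceptor,1.1
TRP,OXT,acceptor,1.1
TRP,CB,hydrophobic,0.7
TRP,CG,aromatic,1.3
TRP,CD1,aromatic,1.3
TRP,CD2,aromatic,1.3
TRP,NE1,donor,1.1
TRP,CE2,aromatic,1.3
TRP,CE3,aromatic,1.3
TRP,CZ2,aromatic,1.3
TRP,CZ3,aromatic,1.3
TRP,CH2,aromatic,1.3
TYR,N,donor,1.1
TYR,CA,none,0.5
TYR,C,none,0.5
TYR,O,acceptor,1.1
TYR,OXT,acceptor,1.1
TYR,CB,hydrophobic,0.7
TYR,CG,aromatic,1.3
TYR,CD1,aromatic,1.3
TYR,CD2,aromatic,1.3
TYR,CE1,aromatic,1.3
TYR,CE2,aromatic,1.3
TYR,CZ,aromatic,1.3
TYR,OH,donor_acceptor,1.4
VAL,N,donor,1.1
VAL,CA,none,0.5
VAL,C,none,0.5
VAL,O,acceptor,1.1
VAL,OXT,acceptor,1.1
VAL,CB,hydrophobic,0.7
VAL,CG1,hydrophobic,0.7
VAL,CG2,hydrophobic,0.7
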