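nitrile	[NX1]#[CX2]
nitro	[$([NX3](=O)=O),$([NX3+](=O)[O-])][!#8]
imine	[$([CX3]([#6])[#6]),$([CX3H][#6])]=[$([NX2][#6]),$([NX2H])]
enamine	[NX3][$(C=C),$(cc)]
ketone	[#6][CX3](=O)[#6]
carbonyl_with_nitrogen	[OX1]=CN
carbonyl_with_oxygen	[CX3](=[OX1])O
thiol	*-[S;D1]
thiocarbonyl	*=[S;D1]
sulfone	[$([#16X4](=[OX1])(=[OX1])([#6])[#6]),$([#16X4+2]([OX1-])([OX1-])([#6])[#6])]
sulfonic_acid	*-[S;D4](=O)(=O)-[O;D1]
sulfonate	[$([#16X4](=[OX1])(=[OX1])([#6])[OX2H0]),$([#16X4+2]([OX1-])([OX1-])([#6])[OX2H0])]
sulfonamide	[$([#16X4]([NX3])(=[OX1])(=[OX1])[#6]),$([#16X4+2]([NX3])([OX1-])([OX1-])[#6])]
acetylene	*-[C;D2]#[C;D1;H]
halogens	*-[#9,#17,#35,#53]
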