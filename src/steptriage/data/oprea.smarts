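# Representative lead-unsuitability (Oprea-style) alerts.
# Synthetic demonstration subset written for this package.
# name<TAB>SMARTS
long_aliphatic_chain	[CH2][CH2][CH2][CH2][CH2][CH2][CH2][CH2]
polyene	[CX3]=[CX3][CX3]=[CX3][CX3]=[CX3]
crown_ether_like	[OX2][CX4][CX4][OX2][CX4][CX4][OX2]
quaternary_ammonium	[NX4+]([#6])([#6])([#6])[#6]
perhalogenated	[CX4]([F,Cl,Br,I])([F,Cl,Br,I])([F,Cl,Br,I])[F,Cl,Br,I]
triphenyl_methyl	[CX4](c1ccccc1)(c1ccccc1)c1ccccc1
polysulfide	[SX2][SX2][SX2]
oxime	[CX3]=[NX2][OX2H]
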