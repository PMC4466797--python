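# Representative reactive/unsuitable-group (Glaxo-style) alerts.
# Synthetic demonstration subset written for this package.
# name<TAB>SMARTS
acyl_halide	[CX3](=[OX1])[F,Cl,Br,I]
sulfonyl_halide	[SX4](=[OX1])(=[OX1])[F,Cl,Br,I]
anhydride	[CX3](=[OX1])[OX2][CX3]=[OX1]
epoxide	C1OC1
aziridine	C1NC1
isocyanate	[NX2]=[CX2]=[OX1]
isothiocyanate	[NX2]=[CX2]=[SX1]
peroxide	[OX2][OX2]
thiocyanate	[SX2]C#N
phosphoryl_halide	[PX4](=[OX1])[F,Cl,Br,I]
alkyl_iodide	[CX4][I]
diazonium	[N+]#N
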