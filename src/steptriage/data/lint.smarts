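# Representative pharma-liability (Pfizer LINT-style) alerts.
# Synthetic demonstration subset written for this package.
# name<TAB>SMARTS
vinyl_ketone	[CX3]=[CX3][CX3](=[OX1])[#6]
acrylamide	[CX3]=[CX3][CX3](=[OX1])[NX3]
nitro_aromatic	[c][NX3+](=[OX1])[OX1-]
hydrazine	[NX3;!$(NC=O)][NX3;!$(NC=O)]
azide	[NX2]=[NX2+]=[NX1-]
n_oxide	[NX4+][OX1-]
phosphonate_ester	[PX4](=[OX1])([OX2][#6])[OX2][#6]
imide	[CX3](=[OX1])[NX3][CX3]=[OX1]
sulfonate_ester	[SX4](=[OX1])(=[OX1])[OX2][#6]
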