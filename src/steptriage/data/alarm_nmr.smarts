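# Representative thiol-reactivity (ALARM NMR-style) alerts.
# Synthetic demonstration subset written for this package.
# name<TAB>SMARTS
maleimide	O=C1C=CC(=O)N1
alpha_halo_ketone	[CX3](=[OX1])[CX4][Cl,Br,I]
disulfide	[SX2][SX2]
nitroso	[NX2]=[OX1]
alpha_beta_unsat_nitrile	[CX3]=[CX3]C#N
haloacetamide	[NX3][CX3](=[OX1])[CX4][Cl,Br,I]
thioester	[SX2][CX3]=[OX1]
aldehyde_reactive	[CX3H1](=O)[#6]
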