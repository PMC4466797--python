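# Representative pan-assay interference (PAINS-style) alerts.
# Synthetic demonstration subset written for this package; full curated lists
# can be supplied by the user as files in the same format.
# name<TAB>SMARTS
quinone_A	O=C1C=CC(=O)C=C1
ortho_quinone	O=C1C(=O)C=CC=C1
catechol_A	[OX2H][c]1[c][c][c][c][c]1[OX2H]
azo_A	[#6]N=N[#6]
hydrazone_A	[#6][CX3]=[NX2][NX3]
ene_rhod_A	S1C(=S)N([#6,#1])C(=O)C1=[CX3]
imine_one_A	[#6][CX3]=[NX2][CX3]=[OX1]
mannich_A	[OX2H][c]([c])[c][CX4][NX3]([CX4])[CX4]
anil_di_alk_A	[NX3]([CX4])([CX4])[c]1[c][c][c]([CX3]=[OX1])[c][c]1
styrene_nitro	[c][CX3]=[CX3][NX3+](=O)[O-]
thio_urea_A	[NX3][CX3](=[SX1])[NX3]
beta_keto_enol	[OX2H][CX3]=[CX3][CX3]=[OX1]
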