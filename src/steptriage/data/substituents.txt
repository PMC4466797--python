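# Substituent grammar for the synthetic library generator.
# name<TAB>SMILES — the first atom of the SMILES is the attachment point.
methyl	C
ethyl	CC
isopropyl	C(C)C
tert-butyl	C(C)(C)C
vinyl	C=C
allyl	CC=C
phenyl	c1ccccc1
benzyl	Cc1ccccc1
hydroxyl	O
methoxy	OC
ethoxy	OCC
carboxylic-acid	C(=O)O
carboxylate	C(=O)[O-]
methyl-ester	C(=O)OC
amide	C(=O)N
acetyl	C(C)=O
formyl	C=O
vinyl-ketone	C(=O)C=C
nitrate-ester	O[N+](=O)[O-]
nitro	[N+](=O)[O-]
amino	N
dimethylamino	N(C)C
acetamido	NC(C)=O
nitrile	C#N
fluoro	F
chloro	Cl
bromo	Br
trifluoromethyl	C(F)(F)F
thiol	S
methylthio	SC
sulfonamide	S(=O)(=O)N
morpholino	N1CCOCC1
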