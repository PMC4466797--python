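# Substructure-fingerprint dictionary (bundled subset of a 307-pattern scheme).
# fragment_id<TAB>name<TAB>SMARTS
SubFP1	Primary carbon	[CX4H3][#6]
SubFP2	Secondary carbon	[CX4H2]([#6])[#6]
SubFP3	Tertiary carbon	[CX4H1]([#6])([#6])[#6]
SubFP5	Alkene	[CX3]=[CX3]
SubFP7	Alkyne	[CX2]#[CX2]
SubFP12	Arene	c
SubFP16	Dialkylether	[OD2]([CX4])[CX4]
SubFP18	Alkylarylether	[OD2]([CX4])[c]
SubFP23	Alcohol	[OX2H][CX4]
SubFP27	Phenol	[OX2H][c]
SubFP33	Aldehyde	[CX3H1](=O)[#6]
SubFP35	Ketone	[#6][CX3](=O)[#6]
SubFP49	Primary amine	[NX3;H2;!$(NC=O)][#6]
SubFP50	Secondary amine	[NX3;H1;!$(NC=O)]([#6])[#6]
SubFP51	Tertiary amine	[NX3;H0;!$(NC=O);!$(N=*);!$(N~[a])]([#6])([#6])[#6]
SubFP66	Nitrile	[NX1]#[CX2]
SubFP75	Thiol	[SX2H]
SubFP77	Thioether	[SX2]([#6])[#6]
SubFP84	Carboxylic acid	[CX3](=O)[OX2H1]
SubFP85	Carboxylic ester	[#6][CX3](=O)[OX2][#6]
SubFP100	Amide	[NX3][CX3](=[OX1])[#6]
SubFP108	Urea	[NX3][CX3](=[OX1])[NX3]
SubFP122	Carbonic acid derivative	[CX3](=[OX1])([OX2])[OX2]
SubFP127	Vinylogous ester	[OX2][CX3]=[CX3][CX3]=[OX1]
SubFP129	Vinylogous carbonyl	[CX3]=[CX3][CX3]=[OX1]
SubFP135	Sulfonamide	[SX4](=[OX1])(=[OX1])[NX3]
SubFP137	Sulfone	[SX4](=[OX1])(=[OX1])([#6])[#6]
SubFP141	Nitro	[$([NX3](=O)=O),$([NX3+](=O)[O-])][!#8]
SubFP171	Aryl fluoride	[F][c]
SubFP172	Aryl chloride	[Cl][c]
SubFP173	Aryl bromide	[Br][c]
SubFP175	Alkyl halide	[F,Cl,Br,I][CX4]
SubFP179	Trifluoromethyl	[CX4](F)(F)F
SubFP187	Nitrate	[OX2][$([NX3](=[OX1])=[OX1]),$([NX3+](=[OX1])[OX1-])]
SubFP210	Aromatic nitrogen	[n]
SubFP211	Aromatic oxygen	[o]
SubFP212	Aromatic sulfur	[s]
SubFP275	Annelated rings	c1ccc2ccccc2c1
SubFP287	Conjugated double bond	[CX3]=[CX3][CX3]=[CX3]
SubFP290	1,3-Tautomerizable	[#6X4;!H0][CX3]=[OX1]
SubFP297	Anion	[$([*-]);!$([*-]~[*+])]
SubFP298	Cation	[$([*+]);!$([*+]~[*-])]
SubFP299	Salt	[!#1;+].[!#1;-]
SubFP303	Michael acceptor	[CX3]=[CX3][$([CX3]=[OX1]),$([SX4](=[OX1])=[OX1]),$(C#N)]
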