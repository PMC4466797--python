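# Pharmacophore feature definitions, schema version 1.
# feature<TAB>SMARTS  (order here fixes the fingerprint bit layout)
donor	[#7,#8,#16;!H0;+0,+1]
acceptor	[$([#8;+0]),$([#7;+0;!X4]),$([#16;+0;X2])]
aromatic	[a]
hydrophobic	[$([C;!$(C~[!#6;!#1]);$(C~[#6])]),$([c;!$(c~[!#6;!#1])]),Cl,Br,I]
positive	[$([*;+;!$([*;+]~[*;-])]),$([N;X3;H2;+0;$(N-[C;X4])])]
negative	[$([*;-;!$([*;-]~[*;+])]),$([O;H1;$(O-C=O)]),$([O;H1;$(O-S(=O)=O)]),$([O;H1;$(O-P(=O))])]
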