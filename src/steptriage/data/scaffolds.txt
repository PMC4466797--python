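# Drug-like scaffold grammar for the synthetic library generator.
# name<TAB>SMILES — substituents are attached to ring atoms that still carry H.
benzene	c1ccccc1
pyridine	c1ccncc1
pyrimidine	c1cncnc1
pyrazine	c1cnccn1
naphthalene	c1ccc2ccccc2c1
quinoline	c1ccc2ncccc2c1
indole	c1ccc2[nH]ccc2c1
furan	c1ccoc1
thiophene	c1ccsc1
pyrrole	c1cc[nH]c1
imidazole	c1cnc[nH]1
pyrazole	c1cc[nH]n1
oxazole	c1cnco1
thiazole	c1cncs1
piperidine	C1CCNCC1
piperazine	C1CNCCN1
morpholine	C1COCCN1
cyclohexane	C1CCCCC1
cyclopentane	C1CCCC1
benzimidazole	c1ccc2[nH]cnc2c1
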