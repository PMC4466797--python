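# Static atomic dipole polarizabilities (10^-24 cm^3), element symbol<TAB>value
H	0.667
B	3.03
C	1.76
N	1.10
O	0.802
F	0.557
Na	24.08
Mg	10.6
Si	5.38
P	3.63
S	2.90
Cl	2.18
K	43.4
Ca	22.8
Fe	8.4
Zn	7.1
Se	3.77
Br	3.05
I	5.35
Li	24.33
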