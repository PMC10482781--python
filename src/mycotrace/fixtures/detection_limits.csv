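element,detection_limit
Ag,0.02
Al,0.02
As,0.2
Ba,0.002
Ca,0.002
Cd,0.02
Co,0.06
Cr,0.02
Cu,0.02
Fe,0.02
Ga,0.06
K,0.02
Li,0.002
Mg,0.002
Mn,0.02
Mo,0.06
Na,0.02
Nb,0.02
Ni,0.06
P,0.2
Pb,0.2
Rb,0.06
S,0.2
Sb,0.2
Se,0.2
Sn,0.2
Sr,0.002
Ti,0.02
V,0.02
W,0.2
Y,0.02
Zn,0.02
Zr,0.02
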