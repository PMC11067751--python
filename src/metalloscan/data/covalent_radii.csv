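# Single-bond covalent radii (Cordero et al. 2008), radius and spread in Angstrom
element,radius,su
H,0.31,0.05
C,0.76,0.01
N,0.71,0.01
O,0.66,0.02
S,1.05,0.03
P,1.07,0.03
Se,1.20,0.04
Mn,1.39,0.05
Fe,1.32,0.03
Cu,1.32,0.04
Zn,1.22,0.04
Ru,1.46,0.07
Re,1.51,0.07
Os,1.44,0.04
Pt,1.36,0.05
Au,1.36,0.06
Hg,1.32,0.05
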