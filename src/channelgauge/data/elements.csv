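element,vdw_radius,mass
H,1.20,1.008
C,1.70,12.011
N,1.55,14.007
O,1.52,15.999
F,1.47,18.998
Na,2.27,22.990
Mg,1.73,24.305
P,1.80,30.974
S,1.80,32.06
Cl,1.75,35.45
K,2.75,39.098
Ca,2.31,40.078
Mn,2.05,54.938
Fe,2.04,55.845
Zn,1.39,65.38
Se,1.90,78.971
Br,1.85,79.904
I,1.98,126.904
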