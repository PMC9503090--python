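element,ionization_potential_ev,electron_affinity_ev
H,13.598,0.754
B,8.298,0.280
C,11.260,1.262
N,14.534,-0.070
O,13.618,1.461
F,17.423,3.401
Si,8.152,1.390
P,10.487,0.746
S,10.360,2.077
Cl,12.968,3.613
As,9.789,0.804
Se,9.752,2.021
Br,11.814,3.364
Sn,7.344,1.112
Te,9.010,1.971
I,10.451,3.059
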