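fragment,contribution,pharmacophore
,0.0,0
C,0.15,0
CC,0.35,0
CCC,0.45,0
C(C)C,0.5,0
C(C)(C)C,0.6,0
N,-0.45,0
N(C)C,-0.35,0
O,-0.3,0
OC,-0.15,0
OCC,-0.1,0
C#N,0.55,0
NC(C)=O,-0.6,0
C(=O)OC,0.3,0
C(=O)N,-0.5,0
F,0.6,1
Cl,0.85,1
Br,1.05,1
C(F)(F)F,1.25,1
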