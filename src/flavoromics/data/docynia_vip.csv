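id,name,vip,p
C17,Octanal,1.102,0.000
C37,Geranylacetone,1.101,0.000
C26,Butyl acetate,1.100,0.002
C36,Dihydro-β-ionone,1.099,0.000
C23,"2,6-Dimethyl-4-heptanone",1.097,0.000
C14,(E)-2-Hexenal,1.097,0.000
C10,"(6Z)-2,6-Dimethylocta-2,6-diene",1.096,0.000
C13,Hexanal,1.094,0.000
C38,β-Ionone,1.094,0.000
C35,Theaspirane,1.090,0.001
C24,"4,6-Dimethylheptan-2-one",1.082,0.001
C18,Benzeneacetaldehyde,1.081,0.002
C25,"4,7,9-Megastigmatrien-3-one",1.070,0.002
C19,(E)-2-Octenal,1.068,0.003
C40,Farnesene,1.060,0.008
C11,1-Octanol,1.059,0.005
C32,Phenethyl acetate,1.059,0.005
C5,4-Methyldodecane,1.022,0.027
C28,Ethyl heptanoate,1.019,0.012
C42,2-Ethylfuran,1.014,0.001
C31,Ethyl caprylate,1.009,0.017
C4,Dodecane,1.009,0.034
C8,"7,9-Dimethylhexadecane",1.001,0.024
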