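name,threshold_mg_per_kg,descriptors
1-Octanol,0.022,green;citrus;floral;sweet
Hexanal,0.005,green;grass;fruity
(E)-2-Hexenal,0.0031,green
Octanal,0.17,orange;green;herbal
Benzeneacetaldehyde,0.0017,sweet;honey;floral
(E)-2-Octenal,0.0027,green;herbal;banana
"2,6-Dimethyl-4-heptanone",9.3,green;fruity;pineapple;banana
Butyl acetate,0.01,fruity;banana
Ethyl heptanoate,0.24,fruity;sweet;banana
Ethyl caprylate,0.04,pineapple;fruity
Phenethyl acetate,0.0067,floral;rosy;sweet;honey
Dihydro-β-ionone,0.0017,cedar;woody;mahogany
Geranylacetone,0.06,rosy;floral;green;fruity
β-Ionone,0.00012,woody;floral;sweet;fruity
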