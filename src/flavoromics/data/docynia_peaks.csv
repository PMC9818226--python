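id,name,cas,formula,class,rt_min,match_score,DY_1,DM_1
C1,4-Methyldecane,2847-72-5,C11H24,alkane,11.69,,0.03,0.02
C2,5-Ethyl-2-methyloctane,62016-18-6,C11H24,alkane,12.70,,0.09,0.06
C3,5-Methylundecane,1632-70-8,C12H26,alkane,12.88,,0.07,0.03
C4,Dodecane,112-40-3,C12H26,alkane,17.06,,0.07,0.04
C5,4-Methyldodecane,6117-97-1,C13H28,alkane,17.65,,0.04,0.02
C6,2-Methyltridecane,1560-96-9,C14H30,alkane,21.55,,0.02,0.01
C7,Tetradecane,629-59-4,C14H30,alkane,22.51,,0.12,0.07
C8,"7,9-Dimethylhexadecane",21164-95-4,C18H38,alkane,25.84,,0.37,0.20
C9,Phytane,638-36-8,C20H42,alkane,31.20,,0.03,0.02
C10,"(6Z)-2,6-Dimethylocta-2,6-diene",2492-22-0,C10H18,alkene,12.56,,0.04,0.15
C11,1-Octanol,111-87-5,C8H18O,alcohol,13.18,,1.88,0.93
C12,3-Hexenal,4440-65-7,C6H10O,aldehyde,5.37,,0.23,0.12
C13,Hexanal,66-25-1,C6H12O,aldehyde,5.42,,0.11,0.31
C14,(E)-2-Hexenal,6728-26-3,C6H10O,aldehyde,6.72,,0.39,1.49
C15,"(E,E)-2,4-Hexadienal",142-83-6,C6H8O,aldehyde,8.36,,0.16,0.11
C16,(E)-2-Heptenal,18829-55-5,C7H12O,aldehyde,9.66,,0.07,0.11
C17,Octanal,124-13-0,C8H16O,aldehyde,11.08,,0.01,0.04
C18,Benzeneacetaldehyde,122-78-1,C8H8O,aldehyde,12.31,,0.03,0.15
C19,(E)-2-Octenal,2548-87-0,C8H14O,aldehyde,12.75,,0.06,0.07
C20,"2,3-Butanedione",431-03-8,C4H6O2,ketone,3.24,,3.76,2.34
C21,2-Heptanone,110-43-0,C7H14O,ketone,7.69,,2.08,1.28
C22,5-Methylhex-4-en-3-one,13905-10-7,C7H12O,ketone,9.73,,0.21,0.11
C23,"2,6-Dimethyl-4-heptanone",108-83-8,C9H18O,ketone,10.09,,4.97,2.61
C24,"4,6-Dimethylheptan-2-one",19549-80-5,C9H18O,ketone,10.61,,0.15,0.08
C25,"4,7,9-Megastigmatrien-3-one",38818-55-2,C13H18O,ketone,27.91,,0.02,0.02
C26,Butyl acetate,123-86-4,C6H12O2,ester,5.73,,0.001,0.03
C27,Butyl butanoate,109-21-7,C8H16O2,ester,10.85,,,0.11
C28,Ethyl heptanoate,106-30-9,C9H18O2,ester,13.97,,10.12,4.87
C29,Methyl octylate,111-11-5,C9H18O2,ester,14.72,,0.12,0.06
C30,Butyl hexanoate,626-82-4,C10H20O2,ester,16.72,,,0.90
C31,Ethyl caprylate,106-32-1,C10H20O2,ester,16.91,,20.29,9.13
C32,Phenethyl acetate,103-45-7,C10H12O2,ester,18.57,,40.69,24.51
C33,Hexyl hexanoate,6378-65-0,C12H24O2,ester,22.08,,,0.72
C34,Benzylcarbinyl caproate,6290-37-5,C14H20O2,ester,28.31,,,0.46
C35,Theaspirane,36431-72-8,C13H22O,terpene,20.33,,12.19,34.90
C36,Dihydro-β-ionone,17283-81-7,C13H22O,terpene,23.34,,0.13,0.70
C37,Geranylacetone,3796-70-1,C13H22O,terpene,23.67,,0.34,0.60
C38,β-Ionone,14901-07-6,C13H20O,terpene,24.49,,0.99,0.27
C39,cis-α-Bergamotene,18252-46-5,C15H24,terpene,24.76,,,0.69
C40,Farnesene,502-61-4,C15H24,terpene,25.16,,0.02,11.38
C41,cis-Bisabolene,53585-13-0,C15H24,terpene,27.27,,,0.26
C42,2-Ethylfuran,3208-16-0,C6H8O,furan,3.59,,0.09,0.04
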