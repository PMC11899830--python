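compound,bp,hf,Mc1,Mc2,Pc1,Pc2
Benzene,80.1,75.2,24,24,4096,4096
Naphthalene,218,141,64,96,192080000,6879707136
Phenanthrene,338,202.7,106,184,7.46807e12,8.70713e15
Anthracene,340,222.6,104,176,6.29408e12,7.2139e15
Chrysene,431,271.1,148,273,2.86774e17,1.102e22
Benzo[a]anthracene,425,277.1,146,265,2.4089e17,9.13009e21
Triphenylene,429,275.1,150,288,2.62144e17,8.30377e21
Tetracene,440,310.5,144,256,2.06244e17,7.56432e21
Benzo[a]pyrene,496,296,184,376,5.35488e20,5.14147e26
Benzo[e]pyrene,493,289.9,182,363,5.15237e20,5.39122e26
Perylene,497,319.2,184,374,5.62449e20,5.14147e26
Anthanthrene,547,323,104,176,6.29408e12,7.2139e15
Benzo[ghi]perylene,542,301.2,218,466,1.04142e24,3.18346e31
"Dibenzo[a,c]anthracene",535,348,190,370,8.3236e21,8.70713e27
"Dibenzo[a,h]anthracene",535,335,188,354,9.21947e21,1.15553e28
"Dibenzo[a,j]anthracene",531,336.3,188,354,9.21947e21,1.15553e28
Picene,519,336.9,190,362,1.10121e22,1.39471e28
Coronene,590,296.7,252,558,1.92829e27,1.97112e36
"Dibenzo(a,h)pyrene",596,375.6,224,456,1.70556e25,5.39122e32
"Dibenzo(a,i)pyrene",594,366,224,456,1.70556e25,5.39122e32
"Dibenzo(a,l)pyrene",595,393.3,226,473,1.62857e25,4.54885e32
Pyrene,393,221.3,140,270,1.5565e16,5.39122e20
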