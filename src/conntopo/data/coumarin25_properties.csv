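compound,BP,MV,E,D,ST,VP,MR,IR,FP,P,PSA
Alternariol,384.6,186.7,63.3,1.2,42.7,0.9,62.5,1.584,161.9,24.8,36
Angelicin,362.6,134.0,60.9,1.4,55.5,0.8,49.9,1.667,173.1,19.8,39
Bergapten,412.4,158.0,66.5,1.4,52.0,1.0,56.6,1.635,203.2,22.4,49
Coumestrol,406.0,167.4,68.3,1.6,79.9,1.0,69.4,1.768,199.3,27.5,80
Daphnetin,430.4,114.0,71.2,1.6,75.6,1.1,43.5,1.689,184.5,17.3,67
Daphnin,670.0,202.6,103.4,1.7,92.6,2.2,77.4,1.689,252.4,30.7,146
Dicumarol,620.7,213.8,96.7,1.6,80.7,1.9,85.4,1.731,231.9,33.9,93
Esculetin,469.7,114.0,76.0,1.6,75.6,1.2,43.5,1.689,201.5,17.3,67
Esculin,697.7,202.6,107.3,1.7,92.6,2.3,77.4,1.689,262.8,30.7,146
Gravelliferone,454.3,267.1,74.1,1.1,43.3,1.2,87.5,1.569,184.9,34.7,47
Herniarin,335.3,141.1,57.8,1.2,44.4,0.7,46.4,1.572,138.6,18.4,36
Imperatorin,448.3,217.5,70.7,1.2,46.7,1.1,75.0,1.606,224.9,29.7,49
Isobergapten,412.4,158.0,66.5,1.4,52.0,1.0,56.6,1.635,203.2,22.4,49
Isopimpinellin,448.7,182.0,70.7,1.4,49.6,1.1,63.3,1.612,225.1,25.1,58
Limettin,388.1,165.1,63.7,1.2,43.0,0.9,53.1,1.557,176.3,21.1,45
Novobiocin,876.2,431.0,133.4,1.4,70.6,0.0,155.3,1.640,483.7,61.6,196
Pimpinellin,441.0,182.0,69.8,1.4,49.6,1.1,63.3,1.612,220.5,25.1,58
Psoralen,362.6,134.0,60.9,1.4,55.5,0.8,49.9,1.667,173.1,19.8,39
Seselin,403.0,186.7,65.4,1.2,42.7,0.9,62.5,1.584,170.5,24.8,36
Skimmin,632.0,204.2,98.2,1.6,81.4,1.9,75.5,1.661,239.3,29.9,126
Umbelliferon,382.1,115.5,65.5,1.4,59.5,0.9,41.6,1.640,181.2,16.5,47
Visnadin,477.7,307.2,74.2,1.3,49.5,1.2,99.3,1.560,206.9,39.4,88
Warfarin,515.2,235.8,82.9,1.3,58.7,1.4,84.4,1.635,188.8,33.5,64
Xanthotoxin,414.8,158.0,66.8,1.4,52.0,1.0,56.6,1.635,204.7,22.4,49
Xanthyletin,340.0,133.9,58.4,1.3,46.4,0.7,45.4,1.593,159.5,18.0,29
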