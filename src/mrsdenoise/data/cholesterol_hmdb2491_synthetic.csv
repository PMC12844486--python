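peak_id,ppm,intensity,provenance
1,0.678,280,position printed; intensity placeholder (upfield angular methyl C18/C19 region)
2,0.745,180,placeholder within stated upfield range (peaks 1-4 below 1.0 ppm)
3,0.876,420,position printed; intensity placeholder (side-chain methyl region)
4,0.930,240,placeholder within stated upfield range (peaks 1-4 below 1.0 ppm)
5,1.007,1000,printed: most intense signal (overlapping methyl/methylene envelope)
6,1.150,320,placeholder within stated 1.1-1.5 ppm range (peaks 6-8)
7,1.300,260,placeholder within stated 1.1-1.5 ppm range (peaks 6-8)
8,1.480,380,placeholder within stated 1.1-1.5 ppm range (peaks 6-8)
9,1.854,220,position printed; intensity placeholder (mid-field ring-junction region)
10,1.970,180,placeholder within stated 1.8-2.3 ppm range (peaks 9-12)
11,2.120,150,placeholder within stated 1.8-2.3 ppm range (peaks 9-12)
12,2.280,130,placeholder within stated 1.8-2.3 ppm range (peaks 9-12)
13,3.500,90,position printed: C3 hydroxyl-bearing methine; intensity placeholder
14,5.350,120,position printed: olefinic C5-C6 proton (source also quotes 5.348/5.356); intensity placeholder
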