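material,energy_keV,mu_over_rho,mu_en_over_rho,density_g_cm3
Al,10,26.23,25.43,2.699
Al,15,7.955,7.487,2.699
Al,20,3.441,3.094,2.699
Al,30,1.128,0.8778,2.699
Al,40,0.5685,0.3601,2.699
Al,50,0.3681,0.1840,2.699
Al,60,0.2778,0.1099,2.699
Al,80,0.2018,0.05511,2.699
Al,100,0.1704,0.03794,2.699
Al,150,0.1378,0.02827,2.699
Cu,10,215.9,148.4,8.960
Cu,15,74.05,57.88,8.960
Cu,20,33.79,27.88,8.960
Cu,30,10.92,9.349,8.960
Cu,40,4.862,4.163,8.960
Cu,50,2.613,2.192,8.960
Cu,60,1.593,1.290,8.960
Cu,80,0.7630,0.5581,8.960
Cu,100,0.4584,0.2949,8.960
Cu,150,0.2217,0.1027,8.960
air,10,5.120,4.742,0.001205
air,15,1.614,1.334,0.001205
air,20,0.7779,0.5389,0.001205
air,30,0.3538,0.1537,0.001205
air,40,0.2485,0.06833,0.001205
air,50,0.2080,0.04098,0.001205
air,60,0.1875,0.03041,0.001205
air,80,0.1662,0.02407,0.001205
air,100,0.1541,0.02325,0.001205
air,150,0.1356,0.02496,0.001205
soft_tissue,10,5.329,4.944,1.060
soft_tissue,15,1.673,1.374,1.060
soft_tissue,20,0.8096,0.5503,1.060
soft_tissue,30,0.3756,0.1557,1.060
soft_tissue,40,0.2683,0.06947,1.060
soft_tissue,50,0.2269,0.04223,1.060
soft_tissue,60,0.2059,0.03190,1.060
soft_tissue,80,0.1837,0.02597,1.060
soft_tissue,100,0.1707,0.02546,1.060
soft_tissue,150,0.1505,0.02764,1.060
table_composite,10,2.373,2.078,1.600
table_composite,15,0.8071,0.5627,1.600
table_composite,20,0.4420,0.2238,1.600
table_composite,30,0.2562,0.06614,1.600
table_composite,40,0.2076,0.03343,1.600
table_composite,50,0.1871,0.02397,1.600
table_composite,60,0.1753,0.02098,1.600
table_composite,80,0.1610,0.02037,1.600
table_composite,100,0.1514,0.02147,1.600
table_composite,150,0.1347,0.02449,1.600
pad_foam,10,5.329,4.944,0.030
pad_foam,15,1.673,1.374,0.030
pad_foam,20,0.8096,0.5503,0.030
pad_foam,30,0.3756,0.1557,0.030
pad_foam,40,0.2683,0.06947,0.030
pad_foam,50,0.2269,0.04223,0.030
pad_foam,60,0.2059,0.03190,0.030
pad_foam,80,0.1837,0.02597,0.030
pad_foam,100,0.1707,0.02546,0.030
pad_foam,150,0.1505,0.02764,0.030
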