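# Photon mass attenuation (mu/rho, with coherent) and mass energy-absorption
# (mu_en/rho) coefficients, cm^2/g, on the standard 10-150 keV grid.
# Values transcribed from the NIST XCOM/Hubbell-Seltzer compilations.
material,energy_keV,mu_rho,mu_en_rho
air,10,5.120,4.742
air,15,1.614,1.334
air,20,0.7779,0.5389
air,30,0.3538,0.1537
air,40,0.2485,0.06833
air,50,0.2080,0.04098
air,60,0.1875,0.03041
air,80,0.1662,0.02407
air,100,0.1541,0.02325
air,150,0.1356,0.02496
water,10,5.329,4.944
water,15,1.673,1.374
water,20,0.8096,0.5503
water,30,0.3756,0.1557
water,40,0.2683,0.06947
water,50,0.2269,0.04223
water,60,0.2059,0.03190
water,80,0.1837,0.02597
water,100,0.1707,0.02546
water,150,0.1505,0.02764
soft_tissue,10,5.364,4.964
soft_tissue,15,1.693,1.396
soft_tissue,20,0.8205,0.5638
soft_tissue,30,0.3783,0.1610
soft_tissue,40,0.2698,0.07192
soft_tissue,50,0.2264,0.04349
soft_tissue,60,0.2048,0.03258
soft_tissue,80,0.1823,0.02615
soft_tissue,100,0.1693,0.02544
soft_tissue,150,0.1492,0.02745
pmma,10,3.357,3.026
pmma,15,1.101,0.8324
pmma,20,0.5714,0.3328
pmma,30,0.3032,0.09645
pmma,40,0.2350,0.04599
pmma,50,0.2074,0.03067
pmma,60,0.1924,0.02530
pmma,80,0.1751,0.02302
pmma,100,0.1641,0.02368
pmma,150,0.1456,0.02657
bone,10,28.51,26.80
bone,15,9.032,8.388
bone,20,4.001,3.601
bone,30,1.331,1.070
bone,40,0.6655,0.4507
bone,50,0.4242,0.2336
bone,60,0.3148,0.1400
bone,80,0.2229,0.06896
bone,100,0.1855,0.04585
bone,150,0.1480,0.03183
aluminum,10,26.23,25.43
aluminum,15,7.955,7.487
aluminum,20,3.441,3.094
aluminum,30,1.128,0.8778
aluminum,40,0.5685,0.3601
aluminum,50,0.3681,0.1840
aluminum,60,0.2778,0.1099
aluminum,80,0.2018,0.05511
aluminum,100,0.1704,0.03794
aluminum,150,0.1378,0.02827
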