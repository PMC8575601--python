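# Mass energy-absorption coefficient of dry air (near sea level),
# transcribed from the standard published compilation of photon mass
# attenuation and mass energy-absorption coefficients.
# Used only for relative air-kerma weighting of spectra.
energy_keV,mu_en_over_rho_cm2_g
5,39.31
6,22.70
8,9.446
10,4.742
15,1.334
20,0.5389
30,0.1537
40,0.06833
50,0.04098
60,0.03041
80,0.02407
100,0.02325
150,0.02496
200,0.02672
300,0.02872
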