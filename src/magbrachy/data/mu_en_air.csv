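# Mass energy-absorption coefficients for dry air (near sea level).
# Compact table on the standard reference grid; log-log interpolated.
# energy_MeV,mu_en_over_rho_cm2_g
0.005,39.75
0.006,22.70
0.008,9.250
0.010,4.742
0.015,1.334
0.020,0.5389
0.030,0.1537
0.040,0.06833
0.050,0.04098
0.060,0.03041
0.080,0.02407
0.100,0.02325
0.150,0.02496
0.200,0.02672
0.300,0.02872
0.400,0.02949
0.500,0.02966
0.600,0.02953
0.800,0.02882
1.000,0.02789
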