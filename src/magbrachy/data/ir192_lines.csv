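# Principal gamma lines of Ir-192 decay (beta-minus to Pt-192 and EC to Os-192).
# Lines with emission intensity >= 0.1% per decay and energy < 1.022 MeV
# (the weak 1061.5 keV line, 0.053%, is omitted; no pair production needed).
# Compiled from standard nuclear decay data.
# energy_MeV,intensity_per_decay
0.136343,0.00200
0.201311,0.00473
0.205794,0.03340
0.283267,0.00266
0.295957,0.28710
0.308455,0.29700
0.316506,0.82860
0.374485,0.00726
0.416469,0.00669
0.468069,0.47840
0.484575,0.03189
0.489060,0.00438
0.588581,0.04522
0.604411,0.08216
0.612462,0.05340
0.885541,0.00291
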