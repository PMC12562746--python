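# Cu complex refractive index, Johnson & Christy, Phys. Rev. B 6, 4370 (1972)
# columns: lambda_um  n  k   (photon energies 0.64-3.00 eV)
0.413281  1.280  2.207
0.430501  1.250  2.305
0.450852  1.240  2.397
0.471423  1.250  2.483
0.495937  1.220  2.564
0.520942  1.180  2.608
0.548603  1.020  2.577
0.582085  0.700  2.704
0.616837  0.300  3.205
0.659490  0.220  3.747
0.704456  0.210  4.205
0.756001  0.240  4.665
0.821087  0.260  5.180
0.891973  0.300  5.768
0.984002  0.320  6.421
1.087581  0.360  7.217
1.215531  0.480  8.245
1.393081  0.600  9.439
1.610184  0.760  11.120
1.937253  1.090  13.430
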