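# Au complex refractive index, Johnson & Christy, Phys. Rev. B 6, 4370 (1972)
# columns: lambda_um  n  k   (photon energies 0.64-3.00 eV)
0.413281  1.460  1.958
0.430501  1.450  1.948
0.450852  1.380  1.914
0.471423  1.310  1.849
0.495937  1.040  1.833
0.520942  0.620  2.081
0.548603  0.430  2.455
0.582085  0.290  2.863
0.616837  0.210  3.272
0.659490  0.140  3.697
0.704456  0.130  4.103
0.756001  0.140  4.542
0.821087  0.160  5.083
0.891973  0.170  5.663
0.984002  0.220  6.350
1.087581  0.270  7.150
1.215531  0.350  8.145
1.393081  0.430  9.519
1.610184  0.560  11.210
1.937253  0.920  13.780
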