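# Ag complex refractive index, Johnson & Christy, Phys. Rev. B 6, 4370 (1972)
# columns: lambda_um  n  k   (photon energies 0.64-3.00 eV)
0.413281  0.050  2.275
0.430501  0.040  2.462
0.450852  0.040  2.657
0.471423  0.050  2.869
0.495937  0.050  3.093
0.520942  0.050  3.324
0.548603  0.060  3.586
0.582085  0.050  3.858
0.616837  0.060  4.152
0.659490  0.050  4.483
0.704456  0.040  4.838
0.756001  0.030  5.242
0.821087  0.040  5.727
0.891973  0.040  6.312
0.984002  0.040  6.992
1.087581  0.040  7.795
1.215531  0.090  8.828
1.393081  0.130  10.100
1.610184  0.150  11.850
1.937253  0.240  14.080
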