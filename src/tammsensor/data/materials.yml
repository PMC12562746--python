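# Default material library.
#
# Each entry maps a material name to exactly one dispersion rule:
#   cauchy:   [A, B_um2, C_um4]   -> n(lambda) = A + B/lambda^2 + C/lambda^4
#   table:    relative path to a 3-column (lambda_um, n, k) text file
#   constant: [n, k]
TiO2:
  cauchy: [2.39513, 0.03471, 0.00835]
SiO2:
  cauchy: [1.46705, 0.00364, -3.049e-6]
glass:
  constant: [1.5, 0.0]
air:
  constant: [1.0, 0.0]
Ag:
  table: jc1972_ag.txt
Au:
  table: jc1972_au.txt
Cu:
  table: jc1972_cu.txt
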