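# AutoDock4 atom-type parameters (AD4.1 bound free-energy model).
# columns: ad_type  Rii[A]  epsii[kcal/mol]  vol[A^3]  solpar  Rij_hb[A]  epsij_hb[kcal/mol]  hbond
# hbond codes: 0 none, 1 donor-H (spherical), 2 donor-H (directional),
#              3 acceptor S (spherical), 4 acceptor A1 (directional N), 5 acceptor A2 (directional O/S)
H    2.00  0.020   0.0000   0.00051  0.0  0.0  0
HD   2.00  0.020   0.0000   0.00051  0.0  0.0  2
HS   2.00  0.020   0.0000   0.00051  0.0  0.0  1
C    4.00  0.150  33.5103  -0.00143  0.0  0.0  0
A    4.00  0.150  33.5103  -0.00052  0.0  0.0  0
N    3.50  0.160  22.4493  -0.00162  0.0  0.0  0
NA   3.50  0.160  22.4493  -0.00162  1.9  5.0  4
NS   3.50  0.160  22.4493  -0.00162  1.9  5.0  3
OA   3.20  0.200  17.1573  -0.00251  1.9  5.0  5
OS   3.20  0.200  17.1573  -0.00251  1.9  5.0  3
F    3.09  0.080  15.4480  -0.00110  0.0  0.0  0
Mg   1.30  0.875   1.5600  -0.00110  0.0  0.0  0
P    4.20  0.200  38.7924  -0.00110  0.0  0.0  0
SA   4.00  0.200  33.5103  -0.00214  2.5  1.0  5
S    4.00  0.200  33.5103  -0.00214  0.0  0.0  0
Cl   4.09  0.276  35.8235  -0.00110  0.0  0.0  0
Ca   1.98  0.550   2.7700  -0.00110  0.0  0.0  0
Mn   1.30  0.875   2.1400  -0.00110  0.0  0.0  0
Fe   1.30  0.010   1.8400  -0.00110  0.0  0.0  0
Zn   1.48  0.550   1.7000  -0.00110  0.0  0.0  0
Br   4.33  0.389  42.5661  -0.00110  0.0  0.0  0
I    4.72  0.550  55.0585  -0.00110  0.0  0.0  0
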