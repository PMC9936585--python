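# Simplified AMBER-parm94-style DNA partial charges (elementary charges).
# This is the package's own charge set: ring/exocyclic values follow the
# published force-field pattern, and each residue's C1' charge absorbs a
# small residual so that totals are exact: -1.0 per nucleotide with
# 5'-phosphate, 0.0 for N3-protonated cytosine (DCP). The DCP minus DC
# base-atom difference sums to exactly +1.0 (the titration proton).
# Override with --charges FILE (same format).

[DA]
N9     -0.026800
C8      0.160700
H8      0.187700
N7     -0.617500
C5      0.072500
C6      0.689700
N6     -0.912300
H61     0.416700
H62     0.416700
N1     -0.762400
C2      0.571600
H2      0.059800
N3     -0.741700
C4      0.380000
P       1.165900
OP1    -0.776100
OP2    -0.776100
O5'    -0.495400
C5'    -0.006900
H5'     0.075400
H5''    0.075400
C4'     0.162900
H4'     0.117600
O4'    -0.369100
C1'     0.043100
H1'     0.183800
C2'    -0.085400
H2'     0.071800
H2''    0.071800
C3'     0.071300
H3'     0.098500
O3'    -0.523200

[DC]
N1     -0.033900
C6     -0.018300
H6      0.229300
C5     -0.522200
H5      0.186300
C4      0.843900
N4     -0.977300
H41     0.431400
H42     0.431400
N3     -0.774800
C2      0.795900
O2     -0.654800
P       1.165900
OP1    -0.776100
OP2    -0.776100
O5'    -0.495400
C5'    -0.006900
H5'     0.075400
H5''    0.075400
C4'     0.162900
H4'     0.117600
O4'    -0.369100
C1'     0.000900
H1'     0.183800
C2'    -0.085400
H2'     0.071800
H2''    0.071800
C3'     0.071300
H3'     0.098500
O3'    -0.523200

[DCP]
N1      0.000000
C6      0.060000
H6      0.260000
C5     -0.400000
H5      0.220000
C4      0.646900
N4     -0.880000
H41     0.460000
H42     0.460000
N3     -0.550000
H3      0.380000
C2      0.800000
O2     -0.520000
P       1.165900
OP1    -0.776100
OP2    -0.776100
O5'    -0.495400
C5'    -0.006900
H5'     0.075400
H5''    0.075400
C4'     0.162900
H4'     0.117600
O4'    -0.369100
C1'     0.000900
H1'     0.183800
C2'    -0.085400
H2'     0.071800
H2''    0.071800
C3'     0.071300
H3'     0.098500
O3'    -0.523200

[DG]
N9      0.057700
C8      0.073600
H8      0.199700
N7     -0.572500
C5      0.199100
C6      0.491800
O6     -0.569900
N1     -0.505300
H1      0.352000
C2      0.743200
N2     -0.923000
H21     0.423500
H22     0.423500
N3     -0.663600
C4      0.181400
P       1.165900
OP1    -0.776100
OP2    -0.776100
O5'    -0.495400
C5'    -0.006900
H5'     0.075400
H5''    0.075400
C4'     0.162900
H4'     0.117600
O4'    -0.369100
C1'     0.026600
H1'     0.183800
C2'    -0.085400
H2'     0.071800
H2''    0.071800
C3'     0.071300
H3'     0.098500
O3'    -0.523200

[DT]
N1     -0.023900
C6     -0.220900
H6      0.260700
C5      0.002500
C7     -0.226900
H71     0.077000
H72     0.077000
H73     0.077000
C4      0.519400
O4     -0.556300
N3     -0.434000
H3      0.342000
C2      0.567700
O2     -0.588100
P       1.165900
OP1    -0.776100
OP2    -0.776100
O5'    -0.495400
C5'    -0.006900
H5'     0.075400
H5''    0.075400
C4'     0.162900
H4'     0.117600
O4'    -0.369100
C1'     0.064600
H1'     0.183800
C2'    -0.085400
H2'     0.071800
H2''    0.071800
C3'     0.071300
H3'     0.098500
O3'    -0.523200
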