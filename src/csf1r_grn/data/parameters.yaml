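_meta:
  description: Calibrated kinetic constants of the CSF1R network model. Activation
    is saturating (Hill); inhibition is multiplicative; LPS activation terms are linear
    in the dimensionless dose so steady-state branches continue smoothly through negative
    LPS. Symbols w/K/n<id> (transcriptional) and wa/Ka/na<id> (post-translational)
    are keyed by the regulation ids of the packaged network table.
  units:
    time: h
    mrna: reference-gene-relative
    lps: dimensionless (1 = experimental dose)
kd_CSF1: 0.133298
b_CSF1: 0.1269
kd_STAT1: 0.099021
b_STAT1: 0.098929
kd_STAT3: 0.115525
b_STAT3: 0.113446
kd_IRF8: 0.16906
b_IRF8: 0.151336
kd_PU1: 0.057762
b_PU1: 0.028879
kd_NFKB: 0.130782
b_NFKB: 0.079243
kd_CEBPA: 0.099021
b_CEBPA: 0.086894
kd_IL6R: 0.086643
b_IL6R: 0.019332
kd_TNFR1: 0.069315
b_TNFR1: 0.038492
kd_CSF1R: 0.057762
b_CSF1R: 0.006235
kd_CSF3R: 0.069315
b_CSF3R: 0.042173
w3: 0.05
K3: 3000.0
n3: 2.0
w4: 0.15
K4: 3000.0
n4: 2.0
w5: 0.72
K5: 2400.0
n5: 4.0
w7: 1.15
K7: 9000.0
n7: 2.0
w8: 0.022
K8: 9000.0
n8: 2.0
w10: 0.1
K10: 3000.0
n10: 2.0
w11: 0.1
K11: 12000.0
n11: 2.0
w12: 0.0834
K12: 647.4
n12: 8.0
w14: 0.0819
K14: 513.6
n14: 6.0
w16: 0.1
K16: 1000.0
n16: 2.0
w17: 0.08
K17: 1000.0
n17: 2.0
w18: 0.5
K18: 9000.0
n18: 2.0
w20: 0.7
K20: 9000.0
n20: 2.0
w22: 0.1
K22: 3000.0
n22: 2.0
w23: 0.0227
K23: 9000.0
n23: 2.0
w24: 0.3
K24: 3000.0
n24: 2.0
w25: 0.2
K25: 12000.0
n25: 2.0
w26: 0.3
K26: 12000.0
n26: 2.0
w27: 0.25
K27: 12000.0
n27: 2.0
w28: 0.15
K28: 12000.0
n28: 2.0
w29: 0.18
K29: 8000.0
n29: 2.0
w30: 0.88
K30: 1650.0
n30: 2.0
w33: 0.06
K33: 1000.0
n33: 2.0
w35: 0.22
K35: 8000.0
n35: 2.0
w36: 0.1
K36: 12000.0
n36: 2.0
w37: 0.3
K37: 8000.0
n37: 2.0
w38: 0.22
K38: 6000.0
n38: 2.0
w40: 0.45
K40: 8000.0
n40: 2.0
K6: 60000.0
n6: 2.0
w2: 0.0419
K15: 0.501
n15: 2.0
wa9: 0.3
Ka9: 20000.0
na9: 2.0
wa13: 0.3
Ka13: 15000.0
na13: 2.0
wa19: 1.5
Ka19: 6000.0
na19: 2.0
wa21: 0.6
Ka21: 15000.0
na21: 2.0
wa31: 0.8
Ka31: 4200.0
na31: 2.0
wa32: 1.2
Ka32: 4200.0
na32: 2.0
wa34: 0.05
Ka34: 6000.0
na34: 2.0
wa39: 0.4
Ka39: 9000.0
na39: 2.0
wa41: 0.4
Ka41: 9000.0
na41: 2.0
wa42: 0.3
Ka42: 15000.0
na42: 2.0
wa1: 2.3
kdp_STAT1: 0.231
ki_STAT1: 1.0
ba_STAT1: 0.02
kdp_STAT3: 0.231
ki_STAT3: 1.0
ba_STAT3: 0.02
kdp_NFKB: 0.231
ki_NFKB: 1.0
ba_NFKB: 0.05
kdp_CEBPA: 0.0937
ki_CEBPA: 1.0
ba_CEBPA: 0.3
kdp_CSF1R: 0.231
ki_CSF1R: 1.0
ba_CSF1R: 0.02
protein_mrna_ratio: 3000.0
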