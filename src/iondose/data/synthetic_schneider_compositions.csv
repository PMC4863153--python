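# Synthetic Schneider-style stoichiometric HU calibration (24 materials / 41 intervals).
# Constructed in-package from ICRU-44-like tissue compositions; NOT the published Schneider et al. (2000) table.
# Replace with a facility-specific CSV of the same columns for clinical-grade calibrations.
material,element,Z,A,mass_fraction
air,C,6,12.011,0.000124009425
air,N,7,14.007,0.755057384
air,O,8,15.999,0.232017633
air,Ar,18,39.948,0.0128009729
lung,H,1,1.008,0.105
lung,C,6,12.011,0.256
lung,N,7,14.007,0.027
lung,O,8,15.999,0.602
lung,Na,11,22.98977,0.001
lung,P,15,30.973762,0.002
lung,S,16,32.06,0.003
lung,Cl,17,35.45,0.002
lung,K,19,39.0983,0.002
adipose,H,1,1.008,0.114
adipose,C,6,12.011,0.598
adipose,N,7,14.007,0.007
adipose,O,8,15.999,0.278
adipose,Na,11,22.98977,0.001
adipose,S,16,32.06,0.001
adipose,Cl,17,35.45,0.001
water,H,1,1.008,0.111906744
water,O,8,15.999,0.888093256
soft_tissue,H,1,1.008,0.105
soft_tissue,C,6,12.011,0.256
soft_tissue,N,7,14.007,0.027
soft_tissue,O,8,15.999,0.602
soft_tissue,Na,11,22.98977,0.001
soft_tissue,P,15,30.973762,0.002
soft_tissue,S,16,32.06,0.003
soft_tissue,Cl,17,35.45,0.002
soft_tissue,K,19,39.0983,0.002
muscle,H,1,1.008,0.102
muscle,C,6,12.011,0.143
muscle,N,7,14.007,0.034
muscle,O,8,15.999,0.71
muscle,Na,11,22.98977,0.001
muscle,P,15,30.973762,0.002
muscle,S,16,32.06,0.003
muscle,Cl,17,35.45,0.001
muscle,K,19,39.0983,0.004
dense_soft,H,1,1.008,0.102
dense_soft,C,6,12.011,0.139
dense_soft,N,7,14.007,0.03
dense_soft,O,8,15.999,0.716
dense_soft,Na,11,22.98977,0.002
dense_soft,P,15,30.973762,0.003
dense_soft,S,16,32.06,0.003
dense_soft,Cl,17,35.45,0.002
dense_soft,K,19,39.0983,0.003
marrow,H,1,1.008,0.105
marrow,C,6,12.011,0.414
marrow,N,7,14.007,0.034
marrow,O,8,15.999,0.439
marrow,P,15,30.973762,0.001
marrow,S,16,32.06,0.002
marrow,Cl,17,35.45,0.002
marrow,K,19,39.0983,0.003
bone_01,H,1,1.008,0.1005625
bone_01,C,6,12.011,0.2496875
bone_01,N,7,14.007,0.0279375
bone_01,O,8,15.999,0.5915625
bone_01,Na,11,22.98977,0.001
bone_01,Mg,12,24.305,0.000125
bone_01,P,15,30.973762,0.0083125
bone_01,S,16,32.06,0.003
bone_01,Cl,17,35.45,0.001875
bone_01,K,19,39.0983,0.001875
bone_01,Ca,20,40.078,0.0140625
bone_02,H,1,1.008,0.096125
bone_02,C,6,12.011,0.243375
bone_02,N,7,14.007,0.028875
bone_02,O,8,15.999,0.581125
bone_02,Na,11,22.98977,0.001
bone_02,Mg,12,24.305,0.00025
bone_02,P,15,30.973762,0.014625
bone_02,S,16,32.06,0.003
bone_02,Cl,17,35.45,0.00175
bone_02,K,19,39.0983,0.00175
bone_02,Ca,20,40.078,0.028125
bone_03,H,1,1.008,0.0916875
bone_03,C,6,12.011,0.2370625
bone_03,N,7,14.007,0.0298125
bone_03,O,8,15.999,0.5706875
bone_03,Na,11,22.98977,0.001
bone_03,Mg,12,24.305,0.000375
bone_03,P,15,30.973762,0.0209375
bone_03,S,16,32.06,0.003
bone_03,Cl,17,35.45,0.001625
bone_03,K,19,39.0983,0.001625
bone_03,Ca,20,40.078,0.0421875
bone_04,H,1,1.008,0.08725
bone_04,C,6,12.011,0.23075
bone_04,N,7,14.007,0.03075
bone_04,O,8,15.999,0.56025
bone_04,Na,11,22.98977,0.001
bone_04,Mg,12,24.305,0.0005
bone_04,P,15,30.973762,0.02725
bone_04,S,16,32.06,0.003
bone_04,Cl,17,35.45,0.0015
bone_04,K,19,39.0983,0.0015
bone_04,Ca,20,40.078,0.05625
bone_05,H,1,1.008,0.0828125
bone_05,C,6,12.011,0.2244375
bone_05,N,7,14.007,0.0316875
bone_05,O,8,15.999,0.5498125
bone_05,Na,11,22.98977,0.001
bone_05,Mg,12,24.305,0.000625
bone_05,P,15,30.973762,0.0335625
bone_05,S,16,32.06,0.003
bone_05,Cl,17,35.45,0.001375
bone_05,K,19,39.0983,0.001375
bone_05,Ca,20,40.078,0.0703125
bone_06,H,1,1.008,0.078375
bone_06,C,6,12.011,0.218125
bone_06,N,7,14.007,0.032625
bone_06,O,8,15.999,0.539375
bone_06,Na,11,22.98977,0.001
bone_06,Mg,12,24.305,0.00075
bone_06,P,15,30.973762,0.039875
bone_06,S,16,32.06,0.003
bone_06,Cl,17,35.45,0.00125
bone_06,K,19,39.0983,0.00125
bone_06,Ca,20,40.078,0.084375
bone_07,H,1,1.008,0.0739375
bone_07,C,6,12.011,0.2118125
bone_07,N,7,14.007,0.0335625
bone_07,O,8,15.999,0.5289375
bone_07,Na,11,22.98977,0.001
bone_07,Mg,12,24.305,0.000875
bone_07,P,15,30.973762,0.0461875
bone_07,S,16,32.06,0.003
bone_07,Cl,17,35.45,0.001125
bone_07,K,19,39.0983,0.001125
bone_07,Ca,20,40.078,0.0984375
bone_08,H,1,1.008,0.0695
bone_08,C,6,12.011,0.2055
bone_08,N,7,14.007,0.0345
bone_08,O,8,15.999,0.5185
bone_08,Na,11,22.98977,0.001
bone_08,Mg,12,24.305,0.001
bone_08,P,15,30.973762,0.0525
bone_08,S,16,32.06,0.003
bone_08,Cl,17,35.45,0.001
bone_08,K,19,39.0983,0.001
bone_08,Ca,20,40.078,0.1125
bone_09,H,1,1.008,0.0650625
bone_09,C,6,12.011,0.1991875
bone_09,N,7,14.007,0.0354375
bone_09,O,8,15.999,0.5080625
bone_09,Na,11,22.98977,0.001
bone_09,Mg,12,24.305,0.001125
bone_09,P,15,30.973762,0.0588125
bone_09,S,16,32.06,0.003
bone_09,Cl,17,35.45,0.000875
bone_09,K,19,39.0983,0.000875
bone_09,Ca,20,40.078,0.1265625
bone_10,H,1,1.008,0.060625
bone_10,C,6,12.011,0.192875
bone_10,N,7,14.007,0.036375
bone_10,O,8,15.999,0.497625
bone_10,Na,11,22.98977,0.001
bone_10,Mg,12,24.305,0.00125
bone_10,P,15,30.973762,0.065125
bone_10,S,16,32.06,0.003
bone_10,Cl,17,35.45,0.00075
bone_10,K,19,39.0983,0.00075
bone_10,Ca,20,40.078,0.140625
bone_11,H,1,1.008,0.0561875
bone_11,C,6,12.011,0.1865625
bone_11,N,7,14.007,0.0373125
bone_11,O,8,15.999,0.4871875
bone_11,Na,11,22.98977,0.001
bone_11,Mg,12,24.305,0.001375
bone_11,P,15,30.973762,0.0714375
bone_11,S,16,32.06,0.003
bone_11,Cl,17,35.45,0.000625
bone_11,K,19,39.0983,0.000625
bone_11,Ca,20,40.078,0.1546875
bone_12,H,1,1.008,0.05175
bone_12,C,6,12.011,0.18025
bone_12,N,7,14.007,0.03825
bone_12,O,8,15.999,0.47675
bone_12,Na,11,22.98977,0.001
bone_12,Mg,12,24.305,0.0015
bone_12,P,15,30.973762,0.07775
bone_12,S,16,32.06,0.003
bone_12,Cl,17,35.45,0.0005
bone_12,K,19,39.0983,0.0005
bone_12,Ca,20,40.078,0.16875
bone_13,H,1,1.008,0.0473125
bone_13,C,6,12.011,0.1739375
bone_13,N,7,14.007,0.0391875
bone_13,O,8,15.999,0.4663125
bone_13,Na,11,22.98977,0.001
bone_13,Mg,12,24.305,0.001625
bone_13,P,15,30.973762,0.0840625
bone_13,S,16,32.06,0.003
bone_13,Cl,17,35.45,0.000375
bone_13,K,19,39.0983,0.000375
bone_13,Ca,20,40.078,0.1828125
bone_14,H,1,1.008,0.042875
bone_14,C,6,12.011,0.167625
bone_14,N,7,14.007,0.040125
bone_14,O,8,15.999,0.455875
bone_14,Na,11,22.98977,0.001
bone_14,Mg,12,24.305,0.00175
bone_14,P,15,30.973762,0.090375
bone_14,S,16,32.06,0.003
bone_14,Cl,17,35.45,0.00025
bone_14,K,19,39.0983,0.00025
bone_14,Ca,20,40.078,0.196875
bone_15,H,1,1.008,0.0384375
bone_15,C,6,12.011,0.1613125
bone_15,N,7,14.007,0.0410625
bone_15,O,8,15.999,0.4454375
bone_15,Na,11,22.98977,0.001
bone_15,Mg,12,24.305,0.001875
bone_15,P,15,30.973762,0.0966875
bone_15,S,16,32.06,0.003
bone_15,Cl,17,35.45,0.000125
bone_15,K,19,39.0983,0.000125
bone_15,Ca,20,40.078,0.2109375
bone_16,H,1,1.008,0.034
bone_16,C,6,12.011,0.155
bone_16,N,7,14.007,0.042
bone_16,O,8,15.999,0.435
bone_16,Na,11,22.98977,0.001
bone_16,Mg,12,24.305,0.002
bone_16,P,15,30.973762,0.103
bone_16,S,16,32.06,0.003
bone_16,Cl,17,35.45,0
bone_16,K,19,39.0983,0
bone_16,Ca,20,40.078,0.225
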