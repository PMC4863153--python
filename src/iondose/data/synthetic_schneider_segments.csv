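# Synthetic Schneider-style stoichiometric HU calibration (24 materials / 41 intervals).
# Constructed in-package from ICRU-44-like tissue compositions; NOT the published Schneider et al. (2000) table.
# Replace with a facility-specific CSV of the same columns for clinical-grade calibrations.
hu_low,hu_high,material,nominal_density,density_slope
-1000.0,-950.0,air,0.00121,0.0
-950.0,-750.0,lung,0.151029,0.00099879
-750.0,-550.0,lung,0.350787,0.00099879
-550.0,-350.0,lung,0.550544,0.00099879
-350.0,-120.0,lung,0.765284,0.00099879
-120.0,-60.0,adipose,0.910109,0.00099879
-60.0,-20.0,adipose,0.960048,0.00099879
-20.0,10.0,water,0.995006,0.00099879
10.0,40.0,soft_tissue,1.015,0.0006
40.0,80.0,muscle,1.036,0.0006
80.0,120.0,dense_soft,1.0762,0.000592
120.0,200.0,marrow,1.11172,0.000592
200.0,313.7931034482759,bone_01,1.169083,0.000592
313.7931034482759,427.58620689655174,bone_01,1.236448,0.000592
427.58620689655174,541.3793103448276,bone_02,1.303814,0.000592
541.3793103448276,655.1724137931035,bone_02,1.371179,0.000592
655.1724137931035,768.9655172413793,bone_03,1.438545,0.000592
768.9655172413793,882.7586206896551,bone_03,1.50591,0.000592
882.7586206896551,996.551724137931,bone_04,1.573276,0.000592
996.551724137931,1110.344827586207,bone_04,1.640641,0.000592
1110.344827586207,1224.1379310344828,bone_05,1.708007,0.000592
1224.1379310344828,1337.9310344827586,bone_05,1.775372,0.000592
1337.9310344827586,1451.7241379310344,bone_06,1.842738,0.000592
1451.7241379310344,1565.5172413793102,bone_06,1.910103,0.000592
1565.5172413793102,1679.310344827586,bone_07,1.977469,0.000592
1679.310344827586,1793.103448275862,bone_07,2.044834,0.000592
1793.103448275862,1906.896551724138,bone_08,2.1122,0.000592
1906.896551724138,2020.6896551724137,bone_08,2.179566,0.000592
2020.6896551724137,2134.4827586206893,bone_09,2.246931,0.000592
2134.4827586206893,2248.2758620689656,bone_09,2.314297,0.000592
2248.2758620689656,2362.0689655172414,bone_10,2.381662,0.000592
2362.0689655172414,2475.862068965517,bone_10,2.449028,0.000592
2475.862068965517,2589.655172413793,bone_11,2.516393,0.000592
2589.655172413793,2703.448275862069,bone_11,2.583759,0.000592
2703.448275862069,2817.2413793103447,bone_12,2.651124,0.000592
2817.2413793103447,2931.0344827586205,bone_12,2.71849,0.000592
2931.0344827586205,3044.8275862068963,bone_13,2.785855,0.000592
3044.8275862068963,3158.620689655172,bone_13,2.853221,0.000592
3158.620689655172,3272.4137931034484,bone_14,2.920586,0.000592
3272.4137931034484,3386.206896551724,bone_15,2.987952,0.000592
3386.206896551724,3500.0,bone_16,3.055317,0.000592
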