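# Proton mass electronic stopping power in liquid water, MeV cm^2/g.
# Values transcribed from the ICRU-49 / PSTAR published tabulation (I = 75 eV);
# used only as a 2% regression guard for the in-package Bethe-Bloch assembly.
E_MeV_u,S_MeV_cm2_g
10,45.67
50,12.45
100,7.289
150,5.445
200,4.492
250,3.911
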