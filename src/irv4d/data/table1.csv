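subject,diaphragm_right_cm,diaphragm_left_cm,com_liver_cm,com_stomach_cm,volvar_heart_pct,volvar_liver_pct,volvar_stomach_pct,simdiff_lungs_pct,simdiff_heart_pct,simdiff_liver_pct
1,1.2,1.5,,,1.9,,,7.4,-8.2,
2,1.4,1.7,0.7,0.5,2.0,1.5,3.0,5.1,-4.6,7.9
3,1.5,1.0,1.2,0.8,1.1,0.7,2.6,8.7,9.2,7.0
4,1.0,2.0,1.0,1.4,3.1,0.9,4.0,6.6,-6.4,7.2
5,1.6,1.1,0.7,0.7,2.6,2.4,3.3,1.1,3.3,-0.3
6,1.6,1.4,1.0,1.0,2.1,1.1,2.1,4.1,3.1,3.0
7,1.2,2.3,1.4,2.0,2.0,0.8,2.7,7.0,-7.0,5.9
8,2.6,2.4,2.3,2.4,2.7,1.7,2.3,5.6,9.2,13.3
9,1.2,1.5,0.9,1.2,1.5,0.8,1.2,,8.6,8.1
10,2.5,1.8,1.6,1.5,6.2,1.1,2.0,1.3,-9.6,1.7
Mean,1.6,1.7,1.2,1.3,2.6,1.2,2.6,5.2,-2.0,6.0
SD,0.6,0.5,0.5,0.6,1.5,0.6,0.8,2.6,7.1,4.1
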