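organ,plasma_volume_L,blood_flow_L_per_min,ace_expression_pct,at1_expression_pct
Arterial Blood,0.35,6.403,0,0
Venous Blood,0.70,6.403,0,0
Brain,0.07,0.70,15,5
Fat,0.12,0.30,6,0
Gonads,0.01,0.003,2,4
Heart,0.06,0.22,0,9
Kidney,0.09,1.10,0,100
Large Intestine,0.06,0.22,2,27
Liver,0.55,1.45,0,76
Lung,0.30,6.403,100,6
Muscle,0.45,1.00,0,8
Pancreas,0.02,0.07,0,0
Plasma,0.15,0.30,6,0
Skin,0.12,0.30,0,57
Spleen,0.06,0.13,0,89
Small Intestine,0.07,0.55,1,27
Stomach,0.02,0.06,3,0
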