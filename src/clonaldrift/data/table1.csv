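case,age,subtype_baseline,subtype_surgical,ki67_baseline,ki67_surgical,ki67_response,allred_baseline,allred_surgical,instability_index,manual_pattern
BRC10,57,LumB,LumA,0.492,0.035,Sensitive,6,4,0.246,
BRC11,84,LumB,LumB,0.25,0.417,Resistant,7,6,0.097,
BRC14,86,LumB,LumA,0.442,0.012,Sensitive,7,4,0,
BRC15,83,LumB,LumA,0.238,0.01,Sensitive,7,7,0.579,
BRC17,63,LumB,LumA,0.32,0.019,Sensitive,7,8,,complex_dynamic
BRC18,85,LumB,LumA,0.125,0,Sensitive,8,7,,complex_dynamic
BRC20,61,LumB,LumB,0.456,0.349,Resistant,4,6,0.856,
BRC21,73,LumA,Normal,0.058,0.019,Sensitive,7,6,1,
BRC22,64,LumA,LumA,0.008,0,Sensitive,6,7,0.533,
BRC24,51,LumB,LumB,0.152,0.155,Resistant,7,7,0.403,
BRC26,71,LumB,LumA,0.101,0.07,Sensitive,7,5,0.499,
BRC30,60,LumB,LumA,0.256,0.183,Resistant,5,5,0.371,
BRC32,54,LumA,LumA,0.1,0,Sensitive,7,6,0.450,
BRC37,56,LumB,LumB,0.76,0.308,Resistant,6,4,0.359,
BRC38,78,LumB,Her2,0.162,0.471,Resistant,8,2,1,
BRC39,79,LumB,LumA,0.356,0.124,Resistant,6,5,0.841,
BRC40,66,LumA,LumA,0.076,0.008,Sensitive,8,8,0.904,
BRC41,55,LumB,LumA,0.412,0.008,Sensitive,8,6,0.535,
BRC42,74,LumB,LumA,0.081,0.022,Sensitive,,8,0.341,
BRC48,66,LumA,LumA,,0.346,Resistant,6,6,,complex_dynamic
BRC49,56,LumA,LumA,0.077,0.152,Resistant,8,8,0.715,
BRC50,78,LumA,LumA,0.195,0.104,Resistant,4,5,0.856,
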