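sample,wgs_case,gene,aa_change,vaf_baseline_pct,vaf_surgical_pct,ki67_baseline,ki67_pt,ki67_response
451180,,ERBB2,p.R599C,4.59,0,0.3,0.125,Resistant
917386,BRC14,ERBB2,p.V777L,26.67,31.55,0.442,0.012,Sensitive
148037,,ERBB2,p.780in_frame_insGSP,2.67,12.35,0.003,0.001,Sensitive
963465,,ERBB2,p.S157F,0,7.21,0.121,0.015,Sensitive
451180,,ESR1,p.E380Q,1.19,3.9,0.3,0.125,Resistant
306707,,ESR1,p.K481N,14.17,39.71,0.266,0.117,Resistant
375938,BRC22,ESR1,p.D538G,0,11.93,0.008,0,Sensitive
255394,BRC39,PIK3CA,p.P104R,52.73,23.81,0.356,0.124,Resistant
702554,,PIK3CA,p.N345K,29.41,34.09,0.6,0.8,Resistant
229684,,PIK3CA,p.G364R,34.33,29.49,0.265,0.002,Sensitive
629051,,PIK3CA,p.E418K,35.06,41.54,0.086,0.01,Sensitive
228281,,PIK3CA,p.C420R,22.58,29.71,0.327,0.015,Sensitive
169316,BRC38,PIK3CA,p.E542K,0,28.95,0.162,0.471,Resistant
434673,BRC42,PIK3CA,p.E542K,10.17,4.55,0.081,0.022,Sensitive
144029,,PIK3CA,p.E545K,16.67,28.57,0.217,,Resistant
306707,,PIK3CA,p.E545K,10.68,38.05,0.266,0.117,Resistant
629051,,PIK3CA,p.E545Q,39.58,29.89,0.086,0.01,Sensitive
228281,,PIK3CA,p.E545K,84.13,26.28,0.387,0.045,Sensitive
412952,BRC39,PIK3CA,p.N1044K,41.11,19.75,0.356,0.124,Resistant
255394,BRC21,PIK3CA,p.H1047R,0,19.28,0.058,0.019,Sensitive
441655,BRC40,PIK3CA,p.H1047R,27.18,27.14,0.076,0.008,Sensitive
956936,BRC37,PIK3CA,p.H1047R,55.52,66.25,0.76,0.308,Resistant
303279,BRC10,PIK3CA,p.H1047R,50,36.27,0.492,0.035,Sensitive
632762,,PIK3CA,p.H1047R,48.84,19.21,0.388,0.268,Resistant
808150,BRC50,PIK3CA,p.H1047L,48.26,45.18,0.195,0.104,Resistant
629834,,PIK3CA,p.H1047R,60,33.73,0.177,0.009,Sensitive
895779,,PIK3CA,p.H1047R,12.04,21.77,0.112,0.029,Sensitive
641677,BRC15,PIK3CA,p.H1047R,37.78,27.17,0.238,0.01,Sensitive
384803,BRC24,PIK3CA,p.H1047R,35.63,24.21,0.152,0.155,Resistant
526430,BRC18,PIK3CA,p.H1047R,23.64,23.58,0.125,0,Sensitive
767881,,PIK3CA,p.H1047R,54.29,32.07,0.091,0.162,Resistant
411144,,PIK3CA,p.H1047R,22.35,2.99,0.3,0.063,Sensitive
251239,,PIK3CA,p.H1047R,45.65,45.45,0.53,0.453,Resistant
439295,,PIK3CA,p.G1049R,23.53,22.16,0.154,0.077,Sensitive
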