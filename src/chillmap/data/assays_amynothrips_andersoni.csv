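species,temperature_c,exposure_h,n_exposed,proportion_dead
Amynothrips andersoni,-3,6,50,0.098
Amynothrips andersoni,-6,6,50,0.24
Amynothrips andersoni,-9,6,50,0.351
Amynothrips andersoni,-12,6,50,0.251
Amynothrips andersoni,-3,12,50,0.02
Amynothrips andersoni,-6,12,50,0.038
Amynothrips andersoni,-9,12,50,0.361
Amynothrips andersoni,-12,12,50,0.58
Amynothrips andersoni,3,24,50,0.547
Amynothrips andersoni,0,24,50,0.036
Amynothrips andersoni,-3,24,50,0.0
Amynothrips andersoni,-6,24,50,0.113
Amynothrips andersoni,-9,24,50,0.253
Amynothrips andersoni,-12,24,50,0.96
Amynothrips andersoni,3,48,50,0.35
Amynothrips andersoni,0,48,50,0.084
Amynothrips andersoni,-3,48,50,0.0
Amynothrips andersoni,-6,48,50,0.191
Amynothrips andersoni,-9,48,50,0.239
Amynothrips andersoni,-12,48,50,1.0
Amynothrips andersoni,3,96,50,0.5
Amynothrips andersoni,0,96,50,0.06
Amynothrips andersoni,-3,96,50,0.0
Amynothrips andersoni,-6,96,50,0.24
Amynothrips andersoni,-9,96,50,0.6
Amynothrips andersoni,-12,96,50,1.0
Amynothrips andersoni,3,192,50,0.723
Amynothrips andersoni,0,192,50,0.06
Amynothrips andersoni,-3,192,50,0.164
Amynothrips andersoni,-6,192,50,0.689
Amynothrips andersoni,3,384,50,0.751
Amynothrips andersoni,0,384,50,0.0
Amynothrips andersoni,-3,384,50,0.4
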