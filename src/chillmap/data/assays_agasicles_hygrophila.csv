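species,temperature_c,exposure_h,n_exposed,proportion_dead
Agasicles hygrophila,2,6,68,0.016
Agasicles hygrophila,-2,6,68,0.05
Agasicles hygrophila,-4,6,68,0.014
Agasicles hygrophila,-6,6,68,0.111
Agasicles hygrophila,2,12,68,0.016
Agasicles hygrophila,-2,12,68,0.203
Agasicles hygrophila,-4,12,68,0.125
Agasicles hygrophila,-6,12,68,0.338
Agasicles hygrophila,2,24,68,0.016
Agasicles hygrophila,-2,24,68,0.333
Agasicles hygrophila,-4,24,68,0.253
Agasicles hygrophila,-6,24,68,0.62
Agasicles hygrophila,2,48,68,0.232
Agasicles hygrophila,-2,48,68,0.554
Agasicles hygrophila,-4,48,68,0.845
Agasicles hygrophila,-6,48,68,0.957
Agasicles hygrophila,2,96,68,0.367
Agasicles hygrophila,-2,96,68,0.922
Agasicles hygrophila,-4,96,68,0.859
Agasicles hygrophila,-6,96,68,1.0
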