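treatment_effect_sd,mean_R2,sd_R2
0.0,0.001136885132194531,0.0002896448965649384
0.1,0.0053388523781715035,0.0005965600551874572
0.2,0.017302288334207865,0.002795275574103808
0.3,0.03630225704225825,0.006615436080580586
0.35,0.046660955671995186,0.006712280150973966
0.4,0.06173698459433068,0.010131813839524249
0.5,0.08894074191179623,0.008630869258378394
0.7,0.1586262776329396,0.02200708559852505
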