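# chamber chemistry samples: daily pH / glucose / acetate per chamber
chamber_id,time_h,pH,glucose_mM,acetate_mM
WE1,0.000000,6.800012,20.000000,0.000000
WE1,24.000000,6.391000,12.510000,7.490000
WE1,48.000000,4.822000,0.310000,19.690000
WE1,72.000000,4.503000,0.000000,20.000000
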