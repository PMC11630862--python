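# coupon table: one row per cleaning cycle per coupon; masses in grams must
# be non-increasing across cycles (oxide stripping cannot add metal)
coupon_id,alloy_label,exposed_area_cm2,density_g_cm3,initial_mass_g,exposure_h,cycle,mass_g
cell1_WE1,UNS G10180,6.52,7.87,25.000000,720,1,24.962000
cell1_WE1,UNS G10180,6.52,7.87,25.000000,720,2,24.955500
cell1_WE1,UNS G10180,6.52,7.87,25.000000,720,3,24.954000
cell1_WE1,UNS G10180,6.52,7.87,25.000000,720,4,24.954000
cell1_WE2,UNS G10180,6.52,7.87,25.000000,720,1,24.950000
cell1_WE2,UNS G10180,6.52,7.87,25.000000,720,2,24.942200
cell1_WE2,UNS G10180,6.52,7.87,25.000000,720,3,24.942000
cell1_WE2,UNS G10180,6.52,7.87,25.000000,720,4,24.942000
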