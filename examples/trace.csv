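# canonical ZRA trace format: hours, amperes (signed; positive = electrons WE1->WE2), volts vs SCE
time_h,current_A,potential_V
0.00,1.2e-06,-0.681
0.25,9.8e-07,-0.681
0.50,-3.1e-07,-0.682
0.75,-2.4e-06,-0.683
1.00,-4.0e-06,-0.684
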