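# treatment configuration: one split-cell experiment
bicarbonate_present: false
inoculated_chamber: WE1     # WE1 | WE2 | none
duration: 720.0             # hours
headspace_label: "N2"
medium:                     # optional; defaults to the standard brine recipe
  nacl: 350.0
  nahco3: 0.0
  cacl2: 25.0
  mgcl2: 15.0
  kcl: 2.0
  k2hpo4: 0.05
  glucose: 20.0
  bicarbonate_present: false
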