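# Trace dialect: declares a potentiostat export's column names and units.
# Dialects are declared, never sniffed.  Supported units:
#   time: h | min | s      current: A | mA | uA | nA      potential: V | mV
time_column: "Time/s"
current_column: "I/mA"
potential_column: "Ewe/mV"
time_unit: s
current_unit: mA
potential_unit: mV
delimiter: ","
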