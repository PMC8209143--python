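# Present-day climate: no deltas, CO2 fixed at 400 ppm.
label: baseline
anchors: {}
co2_anchors:
  1990: 400.0
  2100: 400.0
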