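# Moderate-warming pathway: +1.4 degC by 2070, +1.7 degC by 2100,
# slight mid-century precipitation decrease; CO2 peaking at 538 ppm.
label: moderate_warming
anchors:
  2011:
    temp_delta: 0.0
    precip_factor: 1.0
  2070:
    temp_delta: 1.4
    precip_factor: 0.96
  2100:
    temp_delta: 1.7
    precip_factor: 0.99
co2_anchors:
  2011: 400.0
  2070: 510.0
  2100: 538.0
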