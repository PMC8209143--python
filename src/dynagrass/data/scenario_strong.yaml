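# Strong-warming pathway: +1.9 degC by 2070, +4.4 degC by 2100, drying
# towards late century; CO2 reaching 936 ppm in 2100.
label: strong_warming
anchors:
  2011:
    temp_delta: 0.0
    precip_factor: 1.0
  2070:
    temp_delta: 1.9
    precip_factor: 0.96
  2100:
    temp_delta: 4.4
    precip_factor: 0.90
co2_anchors:
  2011: 400.0
  2070: 677.0
  2100: 936.0
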