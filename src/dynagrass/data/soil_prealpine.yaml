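# Synthetic clay-rich pre-alpine grassland profile (Cambisol-like): topsoil
# values informed by published grassland survey ranges, subsoil horizons
# extrapolated.  Calibration fixture of this package, not survey data.
horizons:
  - upper_cm: 0.0
    lower_cm: 5.0
    bulk_density: 0.55
    ph: 4.9
    c_org: 10.0
    n_org: 1.0
    clay: 58.5
    silt: 35.1
    sand: 6.4
    field_capacity: 52.0
    wilting_point: 22.1
    hydraulic_conductivity: 0.005
    stone_fraction: 1.0
  - upper_cm: 5.0
    lower_cm: 10.0
    bulk_density: 0.82
    ph: 7.1
    c_org: 5.8
    n_org: 0.67
    clay: 58.5
    silt: 35.1
    sand: 6.4
    field_capacity: 52.0
    wilting_point: 22.1
    hydraulic_conductivity: 0.005
    stone_fraction: 1.5
  - upper_cm: 10.0
    lower_cm: 30.0
    bulk_density: 1.0
    ph: 7.2
    c_org: 3.0
    n_org: 0.30
    clay: 50.0
    silt: 40.0
    sand: 10.0
    field_capacity: 46.0
    wilting_point: 21.0
    hydraulic_conductivity: 0.005
    stone_fraction: 2.0
  - upper_cm: 30.0
    lower_cm: 60.0
    bulk_density: 1.2
    ph: 7.4
    c_org: 1.5
    n_org: 0.15
    clay: 45.0
    silt: 40.0
    sand: 15.0
    field_capacity: 42.0
    wilting_point: 20.0
    hydraulic_conductivity: 0.004
    stone_fraction: 3.0
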