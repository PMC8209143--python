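# Default plant parameter set for an intensively cut pre-alpine grassland
# mixture.  Calibrated with scripts/calibrate_defaults.py so that an average
# synthetic weather year under the 4-5 cut regime yields ~10-11 t DM/ha/yr
# with the first cut typically triggered by the target-biomass rule in
# late May.  Versioned calibration fixture of this package.
STORAGE: 0.45
ROOT: 0.90
LEAF: 0.42
STEM: 0.18
CUT: 0.4
GDD: 1000.0
T_BASE: 4.0
GDD_ONSET: 70.0
SLA: 20.0
RUBISCO: 1.0
H2O: 0.5
H2O_SEN: 0.35
LIMIT: 8.0
NC_STORAGE: 0.015
NC_ROOT: 0.012
NC_LEAF: 0.028
NC_STEM: 0.012
NDEF_LEAF: 2.0
N_UPTAKE_MAX: 6.0
YIELD_FRAC: 0.25
R_STORAGE: 0.002
R_ROOT: 0.0075
R_LEAF: 0.015
R_STEM: 0.009
T_REF: 20.0
EXUDATE: 0.20
SEN_DROUGHT: 0.03
SEN_FROST: 0.006
SEN_AGE: 0.006
C_TO_DM: 0.45
kernel:
  amax: 66.0
  par_half: 250.0
  co2_half: 300.0
  k_ext: 0.5
  par_fraction: 0.5
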