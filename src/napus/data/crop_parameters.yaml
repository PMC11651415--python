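# Oilseed rape single-point simulation parameters: published mean / min / max
# for the calibration-relevant subset, plus the wide screening bounds used by
# the sensitivity analysis.  Units follow the WOFOST conventions.
single_point:
  scalars:
    WAV:   {unit: cm,        mean: 42.0,    min: 25.0,    max: 55.0}
    TSUM1: {unit: degC.d,    mean: 701.0,   min: 550.0,   max: 860.0}
    TSUM2: {unit: degC.d,    mean: 737.0,   min: 650.0,   max: 850.0}
    TDWI:  {unit: kg.ha-1,   mean: 8.9,     min: 4.0,     max: 13.0}
    SPA:   {unit: ha.kg-1,   mean: 0.00065, min: 0.00020, max: 0.00090}
    SPAN:  {unit: d,         mean: 37.4,    min: 31.5,    max: 49.5}
    CVL:   {unit: kg.kg-1,   mean: 0.439,   min: 0.220,   max: 0.700}
    CVO:   {unit: kg.kg-1,   mean: 0.612,   min: 0.350,   max: 0.950}
    CVR:   {unit: kg.kg-1,   mean: 0.526,   min: 0.290,   max: 0.700}
    CVS:   {unit: kg.kg-1,   mean: 0.350,   min: 0.200,   max: 0.595}
  # Shoot dry-matter partition coefficients by development stage (DVS).
  # Each row: DVS: [mean, min, max].  The triplet must satisfy
  # FLTB + FSTB + FOTB = 1 at every DVS; means are renormalised on load.
  partition:
    FLTB:
      0.00: [0.94, 0.90, 1.00]
      0.30: [0.90, 0.70, 1.00]
      0.70: [0.34, 0.18, 0.60]
      1.00: [0.16, 0.00, 0.32]
      1.30: [0.04, 0.00, 0.15]
      1.50: [0.00, 0.00, 0.00]
      1.70: [0.00, 0.00, 0.00]
      2.00: [0.00, 0.00, 0.00]
    FOTB:
      0.00: [0.06, 0.00, 0.10]
      0.30: [0.10, 0.00, 0.30]
      0.70: [0.66, 0.40, 0.82]
      1.00: [0.59, 0.45, 0.85]
      1.30: [0.23, 0.05, 0.45]
      1.50: [0.04, 0.00, 0.10]
      1.70: [0.00, 0.00, 0.00]
      2.00: [0.00, 0.00, 0.00]
    FSTB:
      0.00: [0.00, 0.00, 0.00]
      0.30: [0.00, 0.00, 0.00]
      0.70: [0.01, 0.00, 0.10]
      1.00: [0.25, 0.00, 0.48]
      1.30: [0.73, 0.50, 0.90]
      1.50: [0.96, 0.90, 1.00]
      1.70: [1.00, 1.00, 1.00]
      2.00: [1.00, 1.00, 1.00]
# Wide absolute screening bounds per parameter symbol (sensitivity analysis).
screening_bounds:
  TSUMEM: [0.0, 30.0]
  TBASEM: [0.0, 30.0]
  TSUM1:  [500.0, 1000.0]
  TSUM2:  [500.0, 1000.0]
  TDWI:   [0.01, 10.0]
  LAIEM:  [0.0001, 1.0]
  RGRLAI: [0.0001, 1.0]
  SLATB:  [0.0, 0.01]
  SPA:    [0.0, 0.01]
  SPAN:   [20.0, 50.0]
  TBASE:  [-10.0, 10.0]
  KDIFTB: [0.0, 1.0]
  EFFTB:  [0.0, 1.0]
  AMAXTB: [0.0, 60.0]
  TMPFTB: [0.0, 1.0]
  CVL:    [0.2, 1.0]
  CVO:    [0.2, 1.0]
  CVR:    [0.2, 1.0]
  CVS:    [0.2, 1.0]
  RML:    [0.0, 0.1]
  RMO:    [0.0, 0.1]
  RMR:    [0.0, 0.1]
  RMS:    [0.0, 0.1]
  FLTB:   [0.0, 1.0]
  FOTB:   [0.0, 1.0]
  FSTB:   [0.0, 1.0]
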