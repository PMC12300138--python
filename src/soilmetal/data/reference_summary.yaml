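# Published summary statistics for the 72-site paired surface/deep survey of
# the Lingshan agricultural area (Pearl River estuary): per-metal concentration
# range, mean and coefficient of variation by layer, and the published
# two-factor PMF profile matrices (concentration of species, mg/kg).
# These are inputs for desk-scale reproduction checks; the raw 144-sample
# dataset itself is unpublished.
units: mg/kg
n_sites: 72
summary:
  Cu: {surface: {min: 25.90, max: 68.90,  mean: 54.34,  cv: 0.13},
       deep:    {min: 12.00, max: 66.20,  mean: 42.76,  cv: 0.31}}
  Zn: {surface: {min: 99.00, max: 169.00, mean: 132.72, cv: 0.09},
       deep:    {min: 54.00, max: 200.00, mean: 111.61, cv: 0.21}}
  Ni: {surface: {min: 23.60, max: 50.00,  mean: 43.76,  cv: 0.10},
       deep:    {min: 16.80, max: 48.40,  mean: 37.26,  cv: 0.24}}
  Pb: {surface: {min: 27.50, max: 71.80,  mean: 50.43,  cv: 0.14},
       deep:    {min: 23.20, max: 82.50,  mean: 42.94,  cv: 0.23}}
  Cr: {surface: {min: 50.00, max: 97.00,  mean: 86.56,  cv: 0.09},
       deep:    {min: 31.00, max: 100.00, mean: 73.26,  cv: 0.24}}
  Cd: {surface: {min: 0.17,  max: 1.01,   mean: 0.46,   cv: 0.32},
       deep:    {min: 0.11,  max: 1.62,   mean: 0.36,   cv: 0.49}}
  As: {surface: {min: 16.90, max: 41.50,  mean: 28.99,  cv: 0.17},
       deep:    {min: 5.40,  max: 47.60,  mean: 24.27,  cv: 0.31}}
  Hg: {surface: {min: 0.05,  max: 0.23,   mean: 0.14,   cv: 0.21},
       deep:    {min: 0.02,  max: 0.21,   mean: 0.09,   cv: 0.37}}
pmf_profiles:
  # rows: factor 1 (anthropogenic-leaning), factor 2 (natural-leaning)
  metals: [Cu, Zn, Ni, Pb, Cr, Cd, As, Hg]
  surface:
    factor1: [35.60, 58.20, 22.50, 9.62, 47.90, 0.41, 5.64, 0.09]
    factor2: [18.80, 74.20, 21.40, 40.90, 38.60, 0.04, 23.10, 0.04]
  deep:
    factor1: [23.128, 34.885, 15.193, 6.119, 32.276, 0.183, 8.796, 0.05]
    factor2: [19.216, 76.701, 21.952, 36.726, 40.958, 0.158, 13.827, 0.039]
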