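# Hakanson toxic-response coefficients (dimensionless) and ordinal class
# scales for the pollution indices. Boundaries are half-open [lower, upper).
tr:
  Zn: 1
  Cr: 2
  Cu: 5
  Ni: 5
  Pb: 5
  As: 10
  Cd: 30
  Hg: 40
classes:
  igeo:
    # Muller geoaccumulation classes
    bounds: [0, 1, 2, 3, 4, 5]
    labels:
      - unpolluted
      - unpolluted_to_moderate
      - moderate
      - moderate_to_heavy
      - heavy
      - heavy_to_extreme
      - extreme
  er:
    bounds: [40, 80, 160, 320]
    labels: [low, moderate, considerable, high, very_high]
  ri:
    bounds: [150, 300, 600, 1200]
    labels: [low, moderate, strong, very_strong, extreme]
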