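# ICP-MS (aqua-regia digestion) method detection limits.
# 1 ug/g == 1 mg/kg, so these are numerically usable against mg/kg data.
units: ug/g
mdl:
  Cu: 0.01
  Zn: 0.1
  Ni: 0.04
  Pb: 0.005
  Cr: 0.01
  Cd: 0.001
  As: 0.01
  Hg: 0.004
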