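# Crop bioconcentration factors (edible fresh-weight concentration over soil
# concentration, dimensionless) for the crop types grown in the survey region.
# Inflorescence vegetables, sugarcane and banana translocate metals most
# efficiently among the listed crops.
bcf:
  leafy:         {Cu: 0.02,  Zn: 0.05, Ni: 0.01,  Pb: 0.002, Cr: 0.005, Cd: 0.10, As: 0.002, Hg: 0.010}
  fruit:         {Cu: 0.01,  Zn: 0.02, Ni: 0.005, Pb: 0.001, Cr: 0.002, Cd: 0.05, As: 0.001, Hg: 0.005}
  root:          {Cu: 0.015, Zn: 0.03, Ni: 0.008, Pb: 0.002, Cr: 0.004, Cd: 0.08, As: 0.002, Hg: 0.008}
  inflorescence: {Cu: 0.03,  Zn: 0.08, Ni: 0.02,  Pb: 0.004, Cr: 0.008, Cd: 0.15, As: 0.004, Hg: 0.015}
  sugarcane:     {Cu: 0.04,  Zn: 0.10, Ni: 0.03,  Pb: 0.006, Cr: 0.010, Cd: 0.20, As: 0.006, Hg: 0.020}
  banana:        {Cu: 0.03,  Zn: 0.08, Ni: 0.02,  Pb: 0.004, Cr: 0.008, Cd: 0.15, As: 0.004, Hg: 0.015}
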