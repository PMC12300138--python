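# Geochemical background values for Guangdong province soils (China National
# Environmental Monitoring Centre compilation), layer-specific.
units: mg/kg
bgv:
  Cu: {surface: 17.0, deep: 20.4}
  Zn: {surface: 47.3, deep: 51.7}
  Ni: {surface: 14.4, deep: 18.2}
  Pb: {surface: 36.0, deep: 40.1}
  Cr: {surface: 50.5, deep: 58.9}
  Cd: {surface: 0.056, deep: 0.037}
  As: {surface: 8.9, deep: 10.0}
  Hg: {surface: 0.078, deep: 0.053}
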