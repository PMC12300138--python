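# Exposure-factor registry for the dose model, per population.
# Each numeric field is either {value: x}, {normal: {mean, sd}} or
# {triangular: {min, mode, max}}. Normal draws are truncated at zero.
# Conventions follow USEPA exposure-factor handbooks as commonly adapted
# for residential/agricultural scenarios in southern China.
#
# Units: IngR mg/day; InhR m3/day; SA cm2; AF mg/(cm2*day); ABS -; EF days/yr;
# ED years; BW kg; AT_nc / AT_ca days; PEF m3/kg; CF kg/mg; IR_food kg/day.
populations:
  child:
    IngR: {triangular: {min: 100.0, mode: 200.0, max: 300.0}}
    InhR: {value: 7.65}
    SA: {value: 2800.0}
    AF: {value: 0.2}
    ABS: {value: 0.001}
    EF: {triangular: {min: 180.0, mode: 350.0, max: 365.0}}
    ED: {value: 6.0}
    BW: {normal: {mean: 15.9, sd: 2.0}}
    AT_nc: {value: 2190.0}
    AT_ca: {value: 25550.0}
    PEF: {value: 1.36e9}
    CF: {value: 1.0e-6}
    IR_food: {normal: {mean: 0.20, sd: 0.04}}
  adult:
    IngR: {triangular: {min: 50.0, mode: 100.0, max: 200.0}}
    InhR: {value: 14.5}
    SA: {value: 5700.0}
    AF: {value: 0.07}
    ABS: {value: 0.001}
    EF: {triangular: {min: 180.0, mode: 350.0, max: 365.0}}
    ED: {value: 24.0}
    BW: {normal: {mean: 60.6, sd: 8.0}}
    AT_nc: {value: 8760.0}
    AT_ca: {value: 25550.0}
    PEF: {value: 1.36e9}
    CF: {value: 1.0e-6}
    IR_food: {normal: {mean: 0.345, sd: 0.07}}
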