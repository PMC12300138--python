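# Toxicological reference registry.
# rfd: reference doses, mg/(kg*day); sf: cancer slope factors, (mg/(kg*day))^-1.
# Absent (null) entries mean the pathway contributes nothing for that metal.
# The food pathway uses oral values. Sources: USEPA IRIS / RSL compilations
# as conventionally applied in soil health-risk studies.
rfd:
  Cu: {ingest: 0.04,    dermal: 0.012,     inhale: 0.0402,    food: 0.04}
  Zn: {ingest: 0.3,     dermal: 0.06,      inhale: 0.3,       food: 0.3}
  Ni: {ingest: 0.02,    dermal: 0.0054,    inhale: 0.0206,    food: 0.02}
  Pb: {ingest: 0.0035,  dermal: 0.000525,  inhale: 0.00352,   food: 0.0035}
  Cr: {ingest: 0.003,   dermal: 0.00006,   inhale: 0.0000286, food: 0.003}
  Cd: {ingest: 0.001,   dermal: 0.00001,   inhale: 0.001,     food: 0.001}
  As: {ingest: 0.0003,  dermal: 0.000123,  inhale: 0.0003,    food: 0.0003}
  Hg: {ingest: 0.0003,  dermal: 0.000021,  inhale: 0.0000857, food: 0.0003}
sf:
  Cu: {ingest: null,    dermal: null, inhale: null,  food: null}
  Zn: {ingest: null,    dermal: null, inhale: null,  food: null}
  Ni: {ingest: 1.7,     dermal: null, inhale: 0.84,  food: 1.7}
  Pb: {ingest: 0.0085,  dermal: null, inhale: null,  food: 0.0085}
  Cr: {ingest: 0.5,     dermal: null, inhale: 42.0,  food: 0.5}
  Cd: {ingest: 6.1,     dermal: null, inhale: 6.3,   food: 6.1}
  As: {ingest: 1.5,     dermal: 3.66, inhale: 15.1,  food: 1.5}
  Hg: {ingest: null,    dermal: null, inhale: null,  food: null}
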