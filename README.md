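# soilmetal

Pollution assessment, probabilistic human-health risk, and source
apportionment for paired surface/deep agricultural soil heavy-metal surveys.

Agricultural regions downstream of industrialized river deltas accumulate
heavy metals (Cu, Zn, Ni, Pb, Cr, Cd, As, Hg) from industry, traffic and
agrochemicals. Most surveys only sample the plough layer; this package is
built around paired designs that sample each site at two depths (0–20 cm
surface, 150–200 cm deep), so that downward migration of anthropogenic
metals — and the bias it induces in surface-only source apportionment — can
be quantified. It is aimed at environmental geochemists and risk assessors
working with per-sample concentration tables (mg/kg) and standard parameter
registries.

## Methods at its core

- **Pollution indices** per sample and metal against layer-specific
  geochemical backgrounds `Bn`:
  geoaccumulation index `Igeo = log2(Cn / (1.5 Bn))`, contamination factor
  `Cf = Cn/Bn`, Hakanson single-metal potential ecological risk
  `Er = Tr · Cn/Bn`, and the cumulative index `RI = Σ Er`, each with the
  conventional ordinal class scales.
- **Health risk** via the USEPA dose model over four exposure pathways
  (incidental soil ingestion, dermal contact, dust inhalation, and food
  ingestion through crop bioconcentration factors):
  `HQ = ADD/RfD`, `HI = Σ HQ`, `CR = ADD·SF`, `TCR = Σ CR`, deterministically
  and by Monte Carlo (normal/triangular parameter distributions, empirical
  resampling of the concentration term, 10,000 iterations by default) for
  child and adult receptors.
- **Source apportionment** per layer: Pearson correlations, KMO and Bartlett
  adequacy tests, correlation-matrix PCA with eigenvalue>1 retention and
  varimax rotation, and a positive matrix factorization (PMF) receptor model
  `X ≈ G F` (G, F ≥ 0) minimizing the uncertainty-weighted objective
  `Q = Σ ((x_ij − (GF)_ij)/u_ij)²`, with detection-limit-based uncertainty
  matrices, multi-restart solving, and natural/anthropogenic factor
  labelling.
- **Synthetic paired-depth generator** with a known two-source mixing ground
  truth (lognormal scores and noise, per-metal depth attenuation, hotspot and
  pristine sites), so every downstream stage is testable against truth.

## Worked example

```python
from soilmetal import generate, SyntheticConfig, summarize
from soilmetal.core_io import BackgroundValues, DetectionLimits, pair_layers
from soilmetal.pollution_indices import compute_indices
from soilmetal.health_risk import (ExposureParameters, ToxicologicalReference,
                                   BioconcentrationFactors, monte_carlo_risk)
from soilmetal.source_apportionment import (floor_at_mdl, build_uncertainty,
                                            pmf_fit, assign_factor_labels)

table, truth = generate(SyntheticConfig(seed=1))   # 72 sites x 2 layers
idx = compute_indices(table, BackgroundValues.load())
surf = idx[idx.layer == "surface"]
print(surf["er_Cd"].mean().round(1), surf["ri"].mean().round(1))
# 245.7 394.0

mc = monte_carlo_risk(table, ExposureParameters.load(),
                      ToxicologicalReference.load(),
                      BioconcentrationFactors.load(), n_iter=10000, seed=1)
print(mc[("child", "surface")].summary("HI"))
# {'mean': 9.91, 'p05': 3.26, 'p50': 9.01, 'p95': 19.54}

mdl = DetectionLimits.load()
s_mat, d_mat, sites = pair_layers(table)
x = floor_at_mdl(s_mat, mdl)
model = pmf_fit(x, build_uncertainty(x, mdl, 0.1), k=2, n_restarts=20, seed=1)
lab = assign_factor_labels(model, BackgroundValues.load())
print(lab.anthropogenic.round(1).to_dict())
# {'Cu': 65.4, 'Zn': 45.2, 'Ni': 52.0, 'Pb': 0.0, 'Cr': 56.5,
#  'Cd': 100.0, 'As': 0.0, 'Hg': 67.0}
```

Reading the output: mean surface `Er` for Cd is ~246 (very high single-metal
ecological risk, driven by Cd's toxic-response factor of 30 and an ~8-fold
background exceedance), and the mean `RI` of ~394 classes the surface layer
as "strong" cumulative risk. The Monte Carlo hazard index for children
exposed to surface soil has mean ~9.9 (well above the 1.0 safety threshold),
dominated by As and the food-ingestion pathway. The PMF factor labelled
anthropogenic carries ~65% of Cu and ~67% of Hg but none of Pb and As, which
track the natural background — matching the generating truth of the
synthetic dataset.

The same stages run from the shell:

```
soilmetal run --out-dir results_run --seed 1
soilmetal simulate --n-sites 72 --seed 1 --out data.csv
soilmetal indices --in data.csv --out indices.csv
soilmetal risk --in data.csv --iters 10000 --seed 1 --out risk.json
soilmetal sources --in data.csv --layer surface --seed 1 --out sources.json
```

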