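# Methods

## Data model

A survey is a table of per-sample concentrations (mg/kg) for the eight
metals Cu, Zn, Ni, Pb, Cr, Cd, As, Hg, keyed by site, layer (surface =
0–20 cm, deep = 150–200 cm) and crop type. A paired table carries both
layers for every site; layer comparison and per-layer source runs use
matrices aligned on a common site order. Background values are
layer-specific (provincial compilations give different values for topsoil
and parent-material depth) and a registry missing either layer is rejected.
Detection limits declared in µg/g are stored as mg/kg (the units are
numerically equal); values at or below the limit are flagged as censored at
load time but never imputed — how censored values should be treated before
multivariate analysis is left to the analyst, and the default is to leave
them untouched.

## Pollution indices

`Igeo = log2(Cn/(1.5·Bn))` uses the Müller convention: the factor 1.5
absorbs lithogenic variability of the background. `Er = Tr·Cn/Bn` uses the
Hakanson toxic-response factors (Zn 1, Cr 2, Cu/Ni/Pb 5, As 10, Cd 30,
Hg 40) and `RI = Σ Er` over all eight metals; a partial RI is forbidden
because the scale of its class bounds assumes the full metal set. Class
boundaries (Igeo at 0,1,…,5; Er at 40/80/160/320; RI at 150/300/600/1200)
ship as an editable registry; all bands are half-open `[lower, upper)`.
A zero concentration would push Igeo to −∞ and is reported as a
`below_scale` sentinel class rather than propagating −∞.

Indices are computed per sample and summarized by arithmetic means, the way
survey tables report them. Note that the mean of per-sample `Igeo` is not
the `Igeo` of the mean concentration (Jensen gap of the log); comparisons
against published per-mean values use the latter.

## Health risk

Average daily doses follow the USEPA residential equations (see the module
docstring for the four formulas). Non-carcinogenic endpoints average over
the exposure duration (`AT_nc = ED·365` days); carcinogenic endpoints over
a 70-year lifetime (`AT_ca = 25550` days). The food pathway converts the
soil concentration to an edible-tissue concentration with a per-crop
bioconcentration factor and the site's crop assignment; samples without a
crop (`crop_type = "none"`) contribute zero food dose, flagged rather than
erroring. Reference doses and slope factors are per metal × pathway;
absent entries contribute nothing (e.g. no dermal slope factors except As).

Exposure-factor defaults (child: 15.9 kg, 200 mg soil/day, 6-year duration;
adult: 60.6 kg, 100 mg/day, 24 years; EF 350 d/yr; PEF 1.36×10⁹ m³/kg; ABS
0.001) follow USEPA handbook values as commonly adapted for residential
agricultural scenarios in southern China; bioconcentration factors are
regional literature-scale values with inflorescence vegetables, sugarcane
and banana the most efficient translocators. All registries are YAML and
meant to be replaced by study-specific values.

The Monte Carlo layer (default 10,000 iterations) replaces selected factors
by distributions: triangular for intake-type rates (IngR, EF), zero-truncated
normal for body weight and food intake. The concentration term is drawn by
resampling whole sample rows of the layer under analysis, preserving
inter-metal correlation and the site–crop link, rather than fitting a
parametric law the data may not follow. A `concentration="mean"` mode fixes
the term at the layer mean; in that mode a run with all-point distributions
reproduces the deterministic pipeline exactly (the degenerate limit used as
a correctness check — with resampling, the iteration mean still equals the
deterministic value in expectation because all risk quantities are linear in
concentration). One master seed spawns an independent substream per
population × layer, so adding a population does not perturb the others.

Deep-layer risk uses the identical model and should be read as indicative:
there is no direct exposure route to 150–200 cm soil today, but the deep
layer is the parent material of future topsoil and an irrigation-driven
reservoir.

## Source apportionment

Adequacy: KMO from the inverse-correlation partial correlations and the
Bartlett sphericity statistic `−(n−1−(2p+5)/6)·ln det R` (χ², p(p−1)/2 df)
are reported as gates but not enforced. PCA eigendecomposes the correlation
matrix, retains eigenvalues > 1, and varimax-rotates the retained loadings
with Kaiser normalization; component scores use the regression method.
Rotated components are sign-fixed (positive loading sum) and ordered by
explained variance so results are deterministic.

PMF minimizes `Q = Σ((x−GF)/u)²` under `G, F ≥ 0`. Uncertainties follow the
EPA species-uncertainty recipe: `u = sqrt((δ·c)² + (MDL/3)²)` above the
detection limit, else `(5/6)·MDL`, with error fraction δ = 0.1 by default
(δ is a config input and is reported with results). Zero concentrations are
floored at MDL/2 before factorization because the weighting requires
positive data. The solver is a hybrid: 300 multiplicative-update sweeps to
reach the right basin, then alternating exact weighted nonnegative least
squares (per-row and per-column NNLS), each half-sweep an exact minimizer,
so Q is nonincreasing throughout a run; convergence at relative ΔQ < 1e−12
or an absolute exact-fit floor. Twenty random restarts are run and the
lowest Q wins (ties to the lowest restart index). The scaling ambiguity is
resolved by normalizing each factor's scores to mean 1, leaving profiles in
concentration units. Layers are factorized separately; no joint model.

Factor labelling for k = 2: profiles are column-normalized to per-metal
shares and the factor with the larger mean share of Pb and As — the metals
that track the natural background in this setting — is labelled natural.
The two scores are recorded, and labels within 5% relative of each other
are flagged ambiguous. `compare_layers` reports the per-metal
deep-minus-surface anthropogenic percentage.

A two-factor nonnegative factorization is only unique up to a rotation cone
bounded by the zeros of the true profiles and scores. With dense strictly
positive profiles the cone is wide and "the" contributions are not a
well-defined estimand; recovery-style validation is then meaningless. This
is why the synthetic generator (below) anchors the factorization with
tracer zeros.

## Synthetic generator

Each sample is `conc = g_nat·p_nat + a·g_anth·p_anth` times lognormal
measurement noise (CV 0.05), where `a` is a per-metal deep-layer
attenuation applied to the anthropogenic part only. Defaults emulate a
72-site paired survey of an estuarine agricultural region:

- **Profiles.** The anthropogenic source loads on Cd, Cu, Hg, Zn, Ni, Cr
  with surface shares calibrated to published source-apportionment
  percentages for such regions (Cu 65.4 %, Zn 45 %, Ni 51.3 %, Cr 55.4 %,
  Hg 67.3 %); Pb and As are purely natural tracers and Cd a purely
  anthropogenic one. Profile magnitudes are scaled so surface means sit at
  the published concentration scales (e.g. Cd 0.46 mg/kg, As 28.99 mg/kg).
- **Scores.** Lognormal with arithmetic mean 1 (surface) and 0.8 for the
  deep natural score; log-sd 0.25/0.45 (surface natural/anthropogenic) and
  0.30/0.50 (deep). 10 % of sites are hotspots (anthropogenic score ×3,
  natural signal suppressed to a trace — fill-dominated sites) and 5 % are
  pristine plots with only trace anthropogenic input. Score columns are
  rescaled to their configured layer means so this structure redistributes
  rather than inflates the totals.
- **Depth attenuation.** Per-metal defaults solved from target deep
  anthropogenic shares under the deep natural mean of 0.8 (Cu 0.509,
  Zn 0.526, Ni 0.506, Cr 0.430, Hg 0.499, Cd 0.783 from the deep/surface
  mean ratio; Pb/As 1, immaterial for zero loadings).

The tracer zeros and the source-dominated site classes are what make the
two-source factorization essentially unique, so PMF recovery tests have a
well-defined target (noise-free recovery to < 0.1 percentage points;
about 1 point at 5 % noise). The price of this design is realism at the
margins: generated Cd has a wider spread (CV ≈ 1) than published surveys
report (≈ 0.3–0.5), because pristine sites carry almost no Cd and hotspots
a multiple of the mean; deep means for the anthropogenic-heavy metals land
10–25 % below published deep means (a single scalar deep natural mean
cannot match all eight metals); and the generator's As is purely natural,
so it does not emulate the published rise of the anthropogenic As share
with depth. The generator also has no spatial autocorrelation, no
inter-element background correlation beyond the two factors, and no
censoring mechanism. Passing recovery tests therefore demonstrate
correctness of the estimators under the stated mixing model, not
performance on field data with overlapping dense sources.

## Problem sizes and runtime choices

Default runs use 72 paired sites, 10,000 Monte Carlo iterations, and 20 PMF
restarts (a few seconds each on one core). The test suite uses the same
sizes for acceptance-style checks and smaller ones (500–4,000 iterations,
5–10 restarts, 24 sites for pipeline smoke tests) where the property under
test does not depend on scale.

## Known limitations

- Censored (below-detection) values are flagged but not imputed anywhere.
- The dermal route uses the ABS fraction only (no gastrointestinal
  absorption adjustment chain); no age-integrated lifetime risk weighting.
- PMF provides no rotational-ambiguity exploration (Fpeak) or bootstrap
  error estimates; restart Q dispersion is the only stability diagnostic.
- Index class boundaries and all toxicological registries are conventions
  shipped as data, not measurements; conclusions inherit their provenance.
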