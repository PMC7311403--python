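# Methods

## Scope and model idea

`luciav` quantifies how much of the interannual variability (IAV) of the net
land carbon sink S_net is carried by land under human use. It combines three
ingredients that are usually kept separate:

1. a **cohort bookkeeping simulator** that tracks sub-grid land cohorts (one
   land class at one age) through clearing, conversion, abandonment, wood
   harvest, regrowth and an optional shifting-cultivation rotation, and
   resolves the component fluxes E_fire, E_wood, E_legacy and S_recov of net
   land-use-change emissions E_LUC = E_fire + E_wood + E_legacy − S_recov;
2. **climate responsiveness**: every uptake and heterotrophic-respiration
   term is scaled by a linear, zero-clipped function of annual temperature
   and moisture anomalies, with class-specific amplitudes (agricultural >
   secondary > intact). Setting all amplitudes to zero recovers a classical
   bookkeeping model whose output is a fixed superposition of per-event
   response curves;
3. an **attribution pipeline**: the exact identities
   S_net = E_FUEL − S_AIR − S_OCEAN and S_Intact = S_net + E_LUC, the
   variance decomposition
   Var(S_net) = Var(E_LUC) + Var(S_Intact) − 2 Cov(E_LUC, S_Intact),
   covariance allocation, and OLS temperature sensitivities γ on linearly
   detrended anomalies.

The package deliberately contains no vegetation physiology, no grid and no
external data. It is a desk-scale instrument for studying the *mechanism* —
what changes in the attribution when E_LUC is allowed to feel climate — not
for reproducing any particular Earth-system estimate.

## Land state and transitions

Each region holds a list of cohorts with an area (Mha) and carbon densities
(Mg C ha⁻¹) for aboveground biomass (AGB), belowground biomass, litter/slash,
soil, and a *legacy* soil pool inherited from a former land class. Land
classes: intact forest/grassland, secondary forest/grassland, cropland,
pasture, permanent (pre-industrial) agriculture, and fallow secondary forest
inside the shifting-cultivation rotation. Six forest age bins
(1–10, 11–20, 21–40, 41–70, 71–150, >150 yr) and two herbaceous bins
(post-transition vs permanent/intact) are the reporting granularity of
snapshots; internally, cohorts are merged only when they share land class
and exact integer age (area-weighted densities). Merging at coarser
granularity would mix ages and make regrowth depend on an area-weighted mean
age, destroying the exact per-event decomposability that the bookkeeping
limit is tested against.

Transition rules:

- **Clearing to agriculture** drains intact forest first, then secondary
  forest oldest-first. A burned fraction `f_burn` (0.5 tropical, 0.4
  temperate/boreal; only "a certain fraction" is empirically constrained) of
  the cleared AGB is emitted in the clearing year (E_fire); unburned
  residues, roots and the donor's litter become the new cohort's litter.
  Donor soil up to the agricultural equilibrium stays soil; the excess
  becomes legacy soil.
- **Grassland ↔ agriculture** transitions burn nothing — all biomass goes to
  litter — and draw young cohorts first in both directions.
- **Wood harvest** fulfils a prescribed mass starting from intact forest,
  then younger cohorts. The merchantable fraction (`wood_frac = 0.8`) of AGB
  supplies the harvest; branches/leaves and roots go to litter; the
  harvested area re-enters the youngest secondary bin. Fuel wood is emitted
  in the harvest year; industrial wood enters 10- and 100-year product
  pools (50/50 by default; the split is not empirically constrained).
- **Wood-product pools** keep per-vintage accounts. `uniform` mode releases
  `initial/τ` per year and exhausts a vintage after exactly τ steps;
  `exponential` mode releases `remaining·(1 − e^{−1/τ})` per year. Release
  starts in the harvest year. Both modes release the full vintage in the
  limit; cumulative release differs by <10⁻³ of the vintage after 10τ years.
- **Regrowth** follows a Chapman–Richards potential curve
  `B_pot(a) = b_max (1 − e^{−k a})^θ` with θ = 2 and `k` calibrated per
  biome so that the 90%-of-maximum threshold is crossed at the biome age —
  70, 90 and 160 years for tropical (b_max 150 Mg C ha⁻¹), temperate (90)
  and boreal (60). The annual AGB increment is the curve step at the
  cohort's age times the secondary uptake multiplier, clipped at `b_max`;
  roots grow in proportion (`root_shoot = 0.25`).
- **Promotion**: secondary forest reaching 0.9·b_max is relabeled intact and
  thereafter contributes to S_Intact. The same rule is applied to recovering
  grassland against its own maximum (a design choice by symmetry; the
  source rule is stated for forests). Promotion is monotone absent new
  disturbance; fallow cohorts are never promoted.
- **Shifting cultivation** (tropical, 20-year rotation): each year the
  rotation area of *existing* cropland enters fallow (young cropland
  first), and the cropland is replaced by re-clearing mature fallow
  (age ≥ rotation, with clearing fire); only the deficit — during rotation
  ramp-up — is met by clearing intact forest. An optional post-hoc
  relabeling (`relabel_secondary_fraction`) can force a target
  intact/secondary forest composition; the adjustment algorithm is not
  specified in the source analysis, so this minimal area relabeling is this
  package's own construction and changes no carbon pools.

Every operation conserves area exactly and maps each flux one-to-one to a
stock change, so total carbon (land stocks + product pools + cumulative
emissions − cumulative sinks) closes to rounding error (≲10⁻¹² relative)
over multi-century runs.

## Flux accounting and climate modulation

Uptake terms scale with `g = max(0, 1 + α_T T′ + α_W W′)` (α_T < 0, α_W > 0:
hot/dry suppresses uptake) and respiration terms with
`h = max(0, 1 + β_T T′ − β_W W′)` (hot/dry enhances decomposition), with
separate coefficients per land-class group:

- **E_legacy** (opposite of agricultural NBP) = litter and legacy-soil
  decomposition (first-order, ×h) plus the background imbalance
  `Rh_agri·h − NPP_agri·g` of standing agriculture; the background defaults
  are equal (5 Mg C ha⁻¹ yr⁻¹) so mature agriculture is carbon-neutral in a
  neutral year. Crop-harvest export is treated as oxidized in the harvest
  year, i.e. folded into the net NPP term. Permanent pre-industrial
  agriculture is included in E_legacy by definition (a flag-free design:
  its neutral background contributes nothing in the default setup).
- **S_recov** = regrowth uptake (×g) − slash/litter decay (×h) + soil
  relaxation toward the class equilibrium (×g) − legacy-soil decay. It can
  be negative shortly after harvest, when slash decomposition outweighs
  young-stand growth.
- **S_Intact** = intact area × an exogenous background uptake rate
  (linear ramp, 0.05 → 1.0 Mg C ha⁻¹ yr⁻¹ over 1850–2015) × g. The ramp
  stands in for CO₂ fertilization, climate trends and nitrogen deposition,
  whose mechanisms are out of scope; the analysis needs a realistic
  S_Intact magnitude and trend, not its physiology. The uptake is banked in
  intact soil so conservation holds.

Within a year the order is: transitions and harvest → shifting-cultivation
step → wood-product release → regrowth and aging → agricultural, secondary
and intact flux accounting → promotion. Same-year clearing emissions follow
bookkeeping convention; new cohorts grow, and fresh litter decays, already
in their first year.

## Synthetic forcing

The generators emulate the statistical structure of the real forcings
without touching them:

- **Climate**: bivariate AR(1) (lag-1 coefficient 0.5) with innovation sd
  0.17 K (stationary sd ≈ 0.20 K, tropical-belt scale), a 0.004 K yr⁻¹
  warming trend, and moisture anomalies (unit sd) whose innovations
  correlate at −0.6 with temperature — the hot↔dry ENSO coupling. Series
  are mean-centred; fixed seeds give bit-identical output.
- **Schedule**: deforestation rises from ~1.5 Mha yr⁻¹ (1850) to a
  mid-20th-century peak near 7 Mha yr⁻¹ and declines, held
  piecewise-constant over 5-year blocks with mild multiplicative noise —
  mimicking the smoothing of 5-yearly FAO-derived reconstructions, which is
  also why the bookkeeping-limit E_fire has little IAV. Abandonment,
  afforestation, grassland conversion and wood-harvest masses scale
  alongside. The default world is a single tropical macro-region
  (2300 Mha intact forest, 1500 Mha grassland, 300 Mha permanent
  agriculture) spanning 1850–2015, with the attribution window 1959–2015
  (n = 57).
- **Budget**: fossil emissions ramp to 10 Pg C yr⁻¹, the ocean sink is a
  fixed fraction, and atmospheric growth closes the budget so that the
  residual land sink equals a prescribed series *exactly* — the round trip
  through the residual equations is an identity.

What the generator does **not** emulate: spatial structure, the asymmetry
and skew of real ENSO, volcanic cooling events (the 1991–1993 exclusion
hook exists but nothing special happens in those synthetic years), lagged
climate–deforestation interactions, and trade in wood products. Passing
tests therefore demonstrate internal consistency and the qualitative
mechanism, not agreement with any observed series.

## Attribution choices

- Sample moments use the n−1 denominator throughout; the decomposition
  identity is denominator-invariant as long as one is used consistently.
- Variances are computed on linearly detrended series by default (a flag
  restores raw series); the trend is fitted on included years and
  subtracted from all window years.
- γ is the OLS slope of detrended flux anomalies on detrended temperature
  anomalies, with the standard error and two-sided p-value from the slope
  t-test. Because OLS is linear, γ_LAND = γ_Intact − γ_ELUC holds to
  10⁻⁸ whenever the flux identity holds year by year.
- The 1991–1993 exclusion applies to Pearson correlations only (n = 54 in
  the 1959–2015 window); variance decomposition and γ use the full window
  (n = 57). Both are configurable.
- Covariance allocation offers exactly two schemes: `none` (raw shares) and
  `half` (half of the covariance to each side, shares summing to one).

## Calibration of the sensitivity amplitudes

Only the *ordering* of per-area flux IAV — agricultural > secondary >
intact — is empirically grounded; the amplitudes are free constants. They
are stored in `data/default_config.yaml`, not in code, and were calibrated
once so the default world lands in the intended regime: raw E_LUC share of
Var(S_net) ≈ 0.15, half-covariance managed share ≈ 0.35–0.40 (within the
25–45% target band), negative E_LUC–S_Intact covariance, and a bookkeeping
share ≲ 0.03. The resulting γ magnitudes (γ_LAND ≈ −5, γ_Intact ≈ −3,
γ_ELUC ≈ +2 Pg C yr⁻¹ K⁻¹) are larger than observation-based estimates by
roughly 50%, a known consequence of compressing the globe into one tropical
region; the decomposition structure, not the absolute γ, is the object of
study.

## Numerical conventions

- Units: areas Mha, densities Mg C ha⁻¹, fluxes and stocks Pg C
  (1 Mha × 1 Mg C ha⁻¹ = 10⁻³ Pg C). Annual, discrete time.
- Climate multipliers clip at zero; pool withdrawals are capped at the pool
  (`min(k·pool·h, pool)`); the agricultural background flux is capped so
  soil cannot go negative.
- Uniform-mode product vintages track an integer step count and compute the
  remainder as `initial·(1 − steps/τ)`, so exhaustion after exactly τ steps
  is free of accumulated float error.
- Degenerate inputs raise: clearing/harvest beyond the available stock
  (with the deficit named), non-stationary AR(1) coefficients, misaligned
  year indices, zero-variance regressors, windows shorter than 3 years.

## Problem sizes

The default experiment simulates 166 years × 1 region (≈0.3 s); the
conservation checks run two 300-year randomized simulations; the regression
recovery experiment uses 500 replicates of n = 57; the full test suite runs
in well under a minute. These sizes were chosen as the smallest at which the
mechanism and the statistical checks are stable.

## Known limitations

- One region; no spatial heterogeneity, no biome mixing in the default
  world (temperate/boreal parameter sets exist and are exercised in tests).
- No peatland fires, no interannually varying combustion completeness, no
  irrigation, no wood trade — all of which would modify E_fire/E_legacy IAV.
- The background intact sink is exogenous; intact-land IAV is entirely
  multiplicative on that ramp.
- Combining abandonment with grassland conversion routes carbon through the
  young-first priorities, so per-event closed forms only describe schedules
  in which donors keep their initial densities; the general case is checked
  by conservation, not by closed forms.
- The 81%/19% intact/secondary composition adjustment is a bare area
  relabeling; the original adjustment procedure is unspecified.
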