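# Default synthetic world: a single tropical macro-region, 1850-2015, with the
# attribution window 1959-2015 (n = 57) and the 1991-1993 volcanic window
# excluded from correlation diagnostics.
start_year: 1850
end_year: 2015
window: [1959, 2015]
exclude_years: [1991, 1992, 1993]

climate:
  ar1_coef: 0.5          # lag-1 autocorrelation of the anomaly processes
  innovation_sd: 0.17    # K; gives sd(T') ~ 0.20 K, tropical-scale IAV
  trend: 0.004           # K per year warming trend
  wet_coupling: -0.6     # innovation correlation: hot years are dry
  wet_sd: 1.0            # dimensionless moisture anomaly scale

schedule:
  profile: hn_like_rise_decline
  block_years: 5         # FAO-style piecewise-constant smoothing
  block_noise_sd: 0.15
  defor_base: 1.5        # Mha/yr cleared around 1850
  defor_peak: 5.5        # additional Mha/yr at the mid-20th-century peak
  peak_year: 1975
  peak_width: 60.0
  abandon_frac: 0.40     # abandonment relative to clearing, ramping up
  afforest_frac: 0.20
  grass_conv: 2.0        # Mha/yr grassland converted to agriculture
  fuelwood_end: 0.45     # Pg C/yr fuel-wood harvest by 2015
  industrialwood_end: 0.30
  sc_area: 12.0          # Mha/yr in the shifting-cultivation rotation (sc mode)

sc_rotation: 20          # years; tropical fallow cycle

budget:
  e_fuel_end: 10.0       # Pg C/yr fossil+cement emissions by the window end
  ocean_fraction: 0.25

background_sink:         # exogenous intact uptake, Mg C/ha/yr, linear ramp
  r_start: 0.05
  r_end: 1.2

initial_areas:           # Mha; all forest starts intact, agriculture permanent
  intact_forest: 2300.0
  intact_grass: 1500.0
  permanent_agri: 300.0

region:
  biome: tropical
  b_max: 150.0           # Mg C/ha maximum aboveground biomass
  root_shoot: 0.25
  growth_theta: 2.0
  f_burn: 0.5            # fraction of cleared AGB burned in the clearing year
  soil_eq_forest: 100.0  # Mg C/ha
  soil_eq_agri: 60.0
  soil_eq_grass: 80.0
  litter_eq_forest: 6.0
  k_litter: 0.3          # 1/yr litter decomposition
  k_soil_legacy: 0.06    # 1/yr legacy-soil decomposition / soil relaxation
  grass_b_max: 4.0
  wood_frac: 0.8         # merchantable fraction of aboveground biomass
  product_split_10: 0.5  # industrial wood split between 10- and 100-yr pools
  npp_agri: 5.0          # Mg C/ha/yr background agricultural uptake
  rh_agri: 5.0           # Mg C/ha/yr background agricultural respiration

# Climate-sensitivity calibration constants.  Only the ordering
# (agricultural > secondary > intact per-area IAV) is empirically grounded;
# the amplitudes are calibrated so the default world reproduces the
# managed-share regime (raw E_LUC share ~0.25-0.35, half-covariance managed
# share within 0.25-0.45).
sens:
  agri:
    alpha_t: -0.06
    alpha_w: 0.025
    beta_t: 0.06
    beta_w: 0.025
  secondary:
    alpha_t: -0.25
    alpha_w: 0.05
    beta_t: 0.05
    beta_w: 0.025
  intact:
    alpha_t: -0.35
    alpha_w: 0.18
    beta_t: 0.0
    beta_w: 0.0
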