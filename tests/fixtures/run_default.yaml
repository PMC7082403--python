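cells_csv: null
daily_csv: null
frontier:
  cultivar_id: null
  min_bin_count: 20
  width_pct: 5.0
master_seed: 0
model:
  importance_repeats: 10
  k_folds: 6
  pdp_grid_points: 50
  pdp_top_n: 6
  r_cross_max: 0.5
  r_min: 0.15
  rf_params:
    max_depth: null
    max_features: 0.3333333333333333
    min_samples_leaf: 5
    n_estimators: 500
  scenario_ids:
  - A
  - B
  - C
  - D
  seed: 0
  tree_candidates: 25
  tree_max_depth: 3
monthly_csv: null
plots_csv: null
sim:
  age_effect: 0.15
  age_maturity: 5.0
  age_max: 22
  age_min: 1
  base_gap: 0.9
  frontier_slope_true: 57.9
  gap_cap: 1.05
  gap_noise_sd: 0.1
  interannual_srad_sd: 20.0
  interannual_t_sd: 1.3
  interannual_vpd_sd: 3.0
  lat_max: 39.5
  lat_min: 35.0
  li_climate_coef: 0.0003
  li_max: 0.8
  li_noise_sd: 0.03
  li_rate: 0.35
  n_orchards: 33
  plots_per_orchard_year: 24
  seed: 0
  srad_effect: 0.05
  srad_threshold: 450.0
  vpd_effect: 0.012
  vpd_threshold: 40.0
  winter_effect: 0.08
  winter_t_threshold: 10.0
  year_end: 2018
  year_start: 2009
simulate: true
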