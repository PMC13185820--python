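alpha: 0.05
cell_deg: 1.0
dof_correction: overlap
drivers_n_perm: 199
drivers_rf_trees: 200
max_years_per_site: 8
missing_frac: 0.02
n_sites: 300
obs_noise_sd: 50.0
outlier_frac: 0.01
p_high: 90.0
p_low: 10.0
rf_cv_folds: 10
rf_trees: 300
sd_k: 3.0
seed: 7
selection_criterion: bic
selection_direction: both
site_effect_sd: 0.0
train_frac: 0.8
window: 10
world:
  aridity_gradient:
  - 0.12
  - 1.5
  beta_true:
    Chem:
    - 81.0
    - 84.21428571428571
    - 87.42857142857143
    - 90.64285714285714
    - 93.85714285714286
    - 97.07142857142857
    - 100.28571428571429
    - 103.49999999999999
    Chem2:
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    Cli:
    - 90.0
    - 93.57142857142857
    - 97.14285714285714
    - 100.71428571428571
    - 104.28571428571429
    - 107.85714285714285
    - 111.42857142857143
    - 114.99999999999999
    Cli2:
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    Gra:
    - -45.0
    - -46.785714285714285
    - -48.57142857142857
    - -50.357142857142854
    - -52.142857142857146
    - -53.92857142857142
    - -55.714285714285715
    - -57.49999999999999
    Gra2:
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    Mic:
    - 63.0
    - 65.5
    - 68.0
    - 70.5
    - 73.0
    - 75.5
    - 78.0
    - 80.5
    Mic2:
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    Phy:
    - -54.0
    - -56.142857142857146
    - -58.285714285714285
    - -60.42857142857143
    - -62.57142857142858
    - -64.71428571428571
    - -66.85714285714286
    - -69.0
    Phy2:
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    Plant:
    - 315.0
    - 327.5
    - 340.0
    - 352.5
    - 365.0
    - 377.5
    - 390.0
    - 402.49999999999994
    Plant2:
    - 36.0
    - 37.42857142857143
    - 38.857142857142854
    - 40.285714285714285
    - 41.714285714285715
    - 43.14285714285714
    - 44.57142857142857
    - 46.0
    b0:
    - 900.0
    - 960.0
    - 1020.0
    - 1080.0
    - 1140.0
    - 1200.0
    - 1260.0
    - 1320.0
  coupling_mode: decoupled
  grid_cols: 30
  grid_rows: 30
  map_cv: 0.3
  n_ecosystems: 8
  n_years: 34
  noise_sd: 10.0
  npp_noise_cv: 0.06
  pca_sample_size: 2000
  seed: 0
  temp_stability_gradient:
  - 0.25
  - 0.9
  volatility_trend_sd: 1.8
  window: 10
  year0: 1985
year_max: 2018
year_min: 1985
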