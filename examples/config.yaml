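# Full pipeline on the calibrated synthetic trial.
# Costs are USD per 28-day cycle; utilities are literature values.
seed: 7
output_dir: out

survival:
  source: synthetic      # or "files" with per-endpoint curve CSV paths
  n_per_arm: 162
  knot_counts: [0, 1, 2, 3]
  criterion: aic

settings:
  cycle_length_days: 28
  discount_annual: 0.05
  horizon_rule: lifetime # run until 99% of the cohort has died
  max_horizon_years: 40
  half_cycle: true

economics:
  wtp: 40271.00
  # drug_cost_per_cycle / other_cost_per_cycle / utilities / ae_profile
  # default to the tabulated base case; override any subset here.

dsa:
  enabled: true

psa:
  enabled: true
  iterations: 10000

scenarios:
  horizons: [5, 10, 15, 20, null]   # null = lifetime
  alt_utilities: {pfs: 0.736, pd: 0.630}
  regional_wtp:                     # 3x provincial GDP per capita, USD/QALY
    beijing: 95898.55
    shanghai: 91198.89
    zhejiang: 57202.66
    gansu: 22186.50
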