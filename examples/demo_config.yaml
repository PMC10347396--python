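seed: 20230630
synthetic:
  jitter_sd: 0.0
  grid_step_months: 1.0
  risk_grid_months: 3.0
  arms:
    tdxd:
      n: 373
      censor_rate: 0.01
      admin_cutoff: 32.0
      os:
        family: weibull
        shape: 1.3
        median: 23.4
      pfs:
        family: weibull
        shape: 1.1
        median: 9.9
    chemo:
      n: 184
      censor_rate: 0.01
      admin_cutoff: 32.0
      os:
        family: weibull
        shape: 1.3
        median: 16.8
      pfs:
        family: weibull
        shape: 1.1
        median: 5.1
selection:
  criterion: aic
  overrides: {}
economics:
  horizon_cycles: 60
  annual_discount: 0.05
  wtp_per_qaly: 35796.83
  exchange_rate_cny_per_usd: 6.7863
  half_cycle_correction: false
utilities:
  u_pfs: 0.843
  u_pd: 0.6
costs:
  tdxd_per_100mg: 2431.37
  hospitalization_per_cycle: 57.43
  followup_per_cycle: 48.0
  pd_cost_per_cycle: 1886.67
  body_weight_kg: 55.0
  bsa_m2: 1.72
  agents:
    eribulin:
      unit_cost: 360.0
      unit_size_mg: 0.88
    gemcitabine:
      unit_cost: 8.0
      unit_size_mg: 1000.0
psa:
  n_iter: 1000
  sigma_frac: 0.2
ceac_wtp_grid:
  start: 0.0
  stop: 300000.0
  step: 10000.0
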