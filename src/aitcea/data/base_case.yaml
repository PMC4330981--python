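arms:
  five_grass:
    name: 5-grass tablet (SLIT)
    rtss: 3.26
    disc_y1: 0.29
    disc_y2: 0.28
    drug_cost_per_month: 100.0047619047619
    preseasonal_months: 4.0
    visits_per_treatment_year: 3.431544
    injections_per_treatment_year: 0.0
    supervised_first_dose: true
    diagnostic_in_year1: true
  allergoid:
    name: Allergoid mix (SCIT)
    rtss: 3.64
    disc_y1: 0.41
    disc_y2: 0.34
    drug_cost_per_month: 0.0
    preseasonal_months: 0.0
    fixed_annual_drug_cost: 483.2
    visits_per_treatment_year: 5.147447
    injections_per_treatment_year: 8.07012
    supervised_first_dose: false
    diagnostic_in_year1: true
  symptomatic:
    name: Symptomatic treatment
    rtss: 4.47
    disc_y1: 0.0
    disc_y2: 0.0
    drug_cost_per_month: 0.0
    preseasonal_months: 0.0
    visits_per_treatment_year: 0.0
    injections_per_treatment_year: 0.0
    supervised_first_dose: false
    diagnostic_in_year1: false
clinical:
  p_asthma_symptomatic: 0.0046
  rr_asthma_ait: 0.505
  p_death_all: 0.00046
  p_death_asthma: 0.00069
  mean_age_entry: 29.0
utility:
  u_baseline: 0.969974
  k_rtss_slope: 0.05908
  season_months: 3.0
  asthma_decrement: 0.0
  eq5d_ait: 0.976
  eq5d_symptomatic: 0.947
  utility_mode: rsui
costs:
  c_specialist_visit: 13.29
  c_visit_additional: 3.69
  c_injection: 5.11
  c_diagnostics: 20.61
  c_asthma_annual: 186.3
  c_loratadine_ait: 5.14
  c_budesonide_ait: 2.19
  c_loratadine_sympt: 7.54
  c_budesonide_sympt: 3.83
  visits_per_year_off_treatment: 1.9
  c_labour_hour: 30.7
  sick_days_symptomatic: 3.7
  sick_days_ait: 1.2
  productivity_saving_per_season: 133.289
  remuneration_unit_cost_tables:
    lump_sum:
      c_specialist_visit: 13.29
      c_injection: 5.11
      c_diagnostics: 20.61
    ambulatory:
      c_specialist_visit: 13.29
      c_injection: 5.11
      c_diagnostics: 20.61
settings:
  horizon_years: 9
  treatment_years: 3
  cycle_length_years: 1.0
  discount_rate: 0.03
  wtp_grid:
  - 0.0
  - 1000.0
  - 2000.0
  - 3000.0
  - 4000.0
  - 5000.0
  - 6000.0
  - 7000.0
  - 8000.0
  - 9000.0
  - 10000.0
  - 11000.0
  - 12000.0
  - 13000.0
  - 14000.0
  - 15000.0
  - 16000.0
  - 17000.0
  - 18000.0
  - 19000.0
  - 20000.0
  - 21000.0
  - 22000.0
  - 23000.0
  - 24000.0
  - 25000.0
  - 26000.0
  - 27000.0
  - 28000.0
  - 29000.0
  - 30000.0
  - 31000.0
  - 32000.0
  - 33000.0
  - 34000.0
  - 35000.0
  - 36000.0
  - 37000.0
  - 38000.0
  - 39000.0
  - 40000.0
  - 41000.0
  - 42000.0
  - 43000.0
  - 44000.0
  - 45000.0
  - 46000.0
  - 47000.0
  - 48000.0
  - 49000.0
  - 50000.0
  wtp_threshold: 20000.0
  n_psa: 1000
  rng_seed: 20150121
  perspective: payer
  psa_fixed_administration_months: true
  efficacy_se_scale: 0.7673
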