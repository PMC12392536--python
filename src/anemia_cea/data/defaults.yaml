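# Packaged base-case configuration.  Every field is optional; omitted
# fields take these same defaults.  Units: event rates per patient-month,
# hospitalization rate and costs per patient-year, costs in euros.
cohort:
  start_age: 67
  male_fraction: 0.63
  disease_mix:
    diabetes: 0.24
    hypertension_vascular: 0.19
    glomerulonephritis: 0.11
    other: 0.46
anchors:
  s1: 0.857
  s2: 0.755
  s5: 0.474
  tail_annual_mortality_override: null
tiers:
  1:
    inappropriate_esa_rate: 0.1079
    severe_anemia_rate: 0.0490
    rr_inappropriate_esa: 0.37
    rr_severe_anemia: 0.41
    diff_esa_free_months: 0.186
  2:
    inappropriate_esa_rate: 0.0818
    severe_anemia_rate: 0.0316
    rr_inappropriate_esa: 0.49
    rr_severe_anemia: 0.64
    diff_esa_free_months: 0.129
  3:
    inappropriate_esa_rate: 0.0604
    severe_anemia_rate: 0.0217
    rr_inappropriate_esa: 0.66
    rr_severe_anemia: 0.94
    diff_esa_free_months: 0.097
hospitalization:
  base_rate_per_year: 0.836
  arr: 0.126
  drg_cost: 4210.59
hypertension:
  baseline_prevalence: 0.92
  or_esa: 2.10
  atenolol_pack_cost: 23.31
  tablets_per_year: 156
  visit_fee: 18.34
  visits_per_year: 2
economics:
  utility_hd: 0.69
  disutility_severe_anemia: 0.03
  annual_hd_cost_2017: 54604.0
  cpi_factor_2017_to_2024: 1.2375
  esa_annual_cost: 5200.0
  discount_rate: 0.03
scenario:
  acm_effect_duration: lifetime
  prevalent_5y_cohort: false
  qol_effect_enabled: true
  esa_saving_mode: full
  tier: 1
settings:
  horizon_age: 100
  discount_timing: midcycle
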