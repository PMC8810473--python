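# Base-case parameter set: watch-and-wait versus abdominoperineal resection.
# Row names mirror the published parameter tables; values are the printed
# means and standard deviations (2019 US$ for costs). "TME" labels the
# surgical-pathway transition parameters (here, APR).
comparison: WW_vs_APR

transitions:
  perioperative_death: {mean: 0.035, sd: 0.007, family: beta, source: "Marijnen 2002"}
  local_recurrence_2y:
    WW:  {mean: 0.19, sd: 0.04, family: beta, source: "Dossa 2017"}
    TME: {mean: 0.016, sd: 0.003, family: beta, source: "Dossa 2017"}
  local_recurrence_5y:
    WW:  {mean: 0.24, sd: 0.05, family: beta, source: "van der Valk 2018; Smith 2019"}
    TME: {mean: 0.010, sd: 0.002, family: beta, source: "Miller 2020"}
  salvage_given_local:
    WW:  {mean: 0.94, sd: 0.19, family: beta, source: "Dossa 2017"}
    TME: {mean: 0.59, sd: 0.12, family: beta, source: "Ikoma 2017"}
  distant_recurrence_5y:
    WW:  {mean: 0.10, sd: 0.02, family: beta, source: "Dossa 2017"}
    TME: {mean: 0.079, sd: 0.016, family: beta, source: "Dossa 2017"}
  concurrent_distant_given_local: {mean: 0.056, sd: 0.011, family: beta, source: "van der Valk 2018"}
  concurrent_local_given_distant: {mean: 0.17, sd: 0.034, family: beta, source: "van der Valk 2018"}
  distant_after_local_3y: {mean: 0.11, sd: 0.022, family: beta, source: "van der Valk 2018"}
  mortality_local_salvaged_5y: {mean: 0.50, sd: 0.10, family: beta, source: "Rao 2017"}
  mortality_local_unsalvaged_5y: {mean: 0.70, sd: 0.14, family: beta, source: "Rao 2017"}
  mortality_distant_5y: {mean: 0.80, sd: 0.16, family: beta, source: "Rao 2017"}
  mortality_local_and_distant_5y: {mean: 0.80, sd: 0.16, family: beta, source: "Rao 2017"}

utilities:
  initial_ww: {mean: 0.80, sd: 0.16, family: beta, source: "Couwenberg 2018"}
  initial_postop: {mean: 0.110, sd: 0.022, family: beta, source: "van den Brink 2004"}
  salvage_tme_disutility_state: {mean: 0.69, sd: 0.14, family: beta, source: "van den Brink 2004"}
  longterm_apr: {mean: 0.750, sd: 0.15, family: beta, source: "Couwenberg 2018"}
  longterm_lar_with_ostomy: {mean: 0.70, sd: 0.14, family: beta, source: "Couwenberg 2018"}
  longterm_lar_without_ostomy: {mean: 0.78, sd: 0.16, family: beta, source: "Couwenberg 2018"}
  local_recurrence: {mean: 0.67, sd: 0.13, family: beta, source: "van den Brink 2004"}
  distant_recurrence: {mean: 0.70, sd: 0.14, family: beta, source: "van den Brink 2004"}
  local_and_distant: {mean: 0.48, sd: 0.096, family: beta, source: "van den Brink 2004"}
  death: {mean: 0.0, family: fixed}

costs:
  surgery_lar: {mean: 34662.98, sd: 6932.60, family: gamma, source: "Raldow 2019"}
  surgery_apr: {mean: 22015.72, sd: 4403.14, family: gamma, source: "Raldow 2019"}
  adjuvant_chemo_per_cycle: {mean: 1890.00, sd: 378.00, family: gamma, source: "Raldow 2019"}
  ostomy_takedown: {mean: 906.02, sd: 181.20, family: gamma, source: "2019 Physician's Fee Schedule"}
  ostomy_care_monthly: {mean: 93.25, sd: 18.65, family: gamma, source: "2020 DMEPOS Schedule"}
  office_visit: {mean: 25.95, sd: 5.19, family: gamma, source: "2019 Physician's Fee Schedule"}
  rectal_exam: {mean: 9.01, sd: 1.80, family: gamma, source: "2019 Physician's Fee Schedule"}
  flex_sig: {mean: 58.74, sd: 11.75, family: gamma, source: "2019 Physician's Fee Schedule"}
  cea: {mean: 23.41, sd: 4.68, family: gamma, source: "2019 Physician's Fee Schedule"}
  colonoscopy: {mean: 194.97, sd: 38.99, family: gamma, source: "2019 Physician's Fee Schedule"}
  colonoscopy_stoma: {mean: 164.34, sd: 32.87, family: gamma, source: "2019 Physician's Fee Schedule"}
  ct_abd_pelvis: {mean: 323.99, sd: 64.80, family: gamma, source: "2019 Physician's Fee Schedule"}
  ct_chest: {mean: 161.09, sd: 32.22, family: gamma, source: "2019 Physician's Fee Schedule"}
  mri_pelvis: {mean: 405.08, sd: 81.02, family: gamma, source: "2019 Physician's Fee Schedule"}
  restaging_local: {mean: 2100.00, sd: 420.00, family: gamma, source: "Miller 2020"}
  restaging_distant: {mean: 1200.00, sd: 240.00, family: gamma, source: "Miller 2020"}
  reirradiation_course: {mean: 19800.00, sd: 3960.00, family: gamma, source: "Miller 2020"}
  palliative_capecitabine_per_cycle: {mean: 510.00, sd: 102.00, family: gamma, source: "Miller 2020"}
  palliative_mfolfox6_per_cycle: {mean: 850.00, sd: 170.00, family: gamma, source: "Miller 2020"}
  death_perioperative: {mean: 11295.38, sd: 2259.08, family: gamma, source: "Duncan 2019"}
  death_cancer: {mean: 11295.38, sd: 2259.08, family: gamma, source: "Duncan 2019"}
  death_non_cancer: {mean: 11295.38, sd: 2259.08, family: gamma, source: "Duncan 2019"}

timeline:
  cycle_length_months: 1
  horizon_cycles: 60
  annual_discount_rate: 0.03
  postop_recovery_cycles: 2
  adjuvant_chemo_cycles: 4
  adjuvant_chemo_start_offset_cycles: 2
  lar_ostomy_cycles: 6
  wtp_threshold: 100000.0
  cohort_size: 10000
  psa_outer_iterations: 100
  baseline_age_years: 63.0
  ww_adjuvant_chemo: true

life_table: life_table_2015_ssa.csv
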