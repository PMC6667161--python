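schema_version: 1
country: japan
cessation:
  # national cessation data are thin; the China schedule is applied
  male: [[20, 30, 0.0], [30, 66, 0.02], [66, 101, 0.03]]
  female: [[20, 36, 0.0], [36, 101, 0.02]]
cpd:
  # 2007 survey: <10 / 10-19 / 20+ cigarettes per day
  male: {bins: [[1, 9, 0.191], [10, 19, 0.486], [20, null, 0.323]]}
  female: {bins: [[1, 9, 0.344], [10, 19, 0.528], [20, null, 0.128]]}
targets:
  prevalence_year: 2010
  prevalence: {male: 0.266, female: 0.093}
  mortality_year: 2012
  mortality_deaths: {male: 53976, female: 21367}
population:
  anchors: {2020: 125507472, 2030: 120751317, 2040: 114448328}
  median_age: 48.4
  pyramid_seed: 12
other_cause:
  makeham:
    male: [0.0008, 4.0e-05, 1.092]
    female: [0.0005, 2.0e-05, 1.096]
  # scaled so the implied life expectancy at birth matches the
  # published 2020 sex-specific values for this country
  ratio: {male: 0.779, female: 0.694}
  # non-lung-cancer mortality of smokers relative to never smokers
  smoker_rr_20cpd: 2.0
  quit_rr_halflife: 7.0
natural_history:
  baseline_age0: 35.0
  baseline_power: 2.0
  baseline_plateau_age: 80.0
  err_per_pack_year: 0.4
  quit_halflife: 15.0
  sojourn_mean: 4.0
  early_frac_clinical: 0.25
  cure_early: 0.1
  cure_late: 0.01
  q_early: 0.135
  q_late: 0.45
initiation:
  peak_age: {male: 19.0, female: 19.0}
  width: 4.5
  min_age: 10
  max_age: 40
calibrated: null
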