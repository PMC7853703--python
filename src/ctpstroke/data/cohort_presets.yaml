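# Cohort presets for the two admission periods.
#
# Continuous volume models are parameterised by printed medians and
# inter-quartile ranges (ml).  A q1 of 0 selects a zero-inflated log-normal
# with a 25% point mass at zero, so that the first quartile of the sampled
# population is 0 as printed.  Categorical probabilities are the printed
# frequencies.
covid_2020:
  period: COVID
  n: 30
  total_volume: {median: 83.3, q1: 22.0, q3: 187.8}
  core_volume: {median: 27.8, q1: 0.0, q3: 120.2, p_zero: 0.25}
  infarct_volume: {median: 35.5, q1: 3.0, q3: 150.8}
  nihss: {median: 11, q1: 4, q3: 17}
  age: {median: 76, q1: 68, q3: 82}
  p_female: 0.533     # 16 F of 30
  p_lvo: 0.533        # 16 of 30
  p_suso: 0.300       # 9 of 30
  risk_factors:
    hypertension: 0.833      # 25 of 30
    diabetes: 0.400          # 12 of 30
    dyslipidemia: 0.600      # 18 of 30
    atrial_fibrillation: 0.467   # 14 of 30
    ischemic_cardiomyopathy: 0.233  # 7 of 30

no_covid_2019:
  period: no-COVID
  n: 51
  total_volume: {median: 18.5, q1: 3.5, q3: 77.2}
  core_volume: {median: 1.0, q1: 0.0, q3: 15.9, p_zero: 0.25}
  infarct_volume: {median: 3.0, q1: 0.0, q3: 28.3, p_zero: 0.25}
  nihss: {median: 6, q1: 4, q3: 15}
  age: {median: 76, q1: 72, q3: 83}
  p_female: 0.431     # 22 F of 51
  p_lvo: 0.333        # 17 of 51
  p_suso: 0.176       # 9 of 51
  risk_factors:
    hypertension: 0.804      # 41 of 51
    diabetes: 0.353          # 18 of 51
    dyslipidemia: 0.647      # 33 of 51
    atrial_fibrillation: 0.392   # 20 of 51
    ischemic_cardiomyopathy: 0.314  # 16 of 51
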