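# Virtual-population demographics for severe hemophilia A (all male).
#
# Hierarchical generative model: stratum (child < 12 y) ~ Bernoulli;
# age from a stratum-specific distribution; body weight log-normal around an
# age-dependent median growth curve; BMI log-normal around an age-dependent
# median; fat-free mass derived from age/weight/BMI (Al-Sallami male formula).
# Values calibrated once so that a 10,000-patient draw matches the target
# cohort summaries (median age ~24 y, ~11.7% children <12 y, median body
# weight ~70.7 kg, median BMI ~23.7, median FFM ~55.6 kg).
child_fraction: 0.1167
age:
  min: 3.0
  max: 72.0
  child:             # age | child ~ 3 + 9 * Beta(a, b)  (median ~ 9.3 y)
    beta_a: 2.4
    beta_b: 1.2
  adult:             # age | adult ~ LogNormal, truncated to [12, 72]
    median: 24.0
    sigma_log: 0.80
weight:
  min: 14.5
  max: 150.0
  sigma_log_child: 0.16
  sigma_log_adult: 0.20
  # median growth curve m(age), log-linear interpolation between knots
  median_knots:
    age: [3.0, 12.0, 19.0, 72.0]
    weight: [15.5, 52.0, 77.0, 77.0]
bmi:
  min: 10.4
  max: 51.1
  sigma_log_child: 0.12
  sigma_log_adult: 0.18
  median_knots:
    age: [3.0, 12.0, 25.0, 72.0]
    bmi: [17.5, 20.7, 24.5, 24.5]
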