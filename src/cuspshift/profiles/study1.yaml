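# Synthetic condition calibrated to the Waldo Canyon sample descriptives
# (three waves ~30 days apart, n = 189, loss as the asymmetry source).
n_subjects: 189
study_profile: study1
wave_labels: [T1, T2, T3]
wave_days: [0.0, 30.0, 60.0]
gender_p_female: 0.688
asymmetry_source: loss
covariates:
  cse: {mean: 5.37, sd: 1.16, lo: 1.0, hi: 7.0, loading: -0.65}
  loss: {mean: 0.89, sd: 0.64, lo: 0.0, hi: 4.0, loading: 0.57}
  time_since: {mean: 63.16, sd: 9.88, lo: 0.0, hi: .inf, loading: 0.0}
b0: 1.2
b1: -0.8
a0: 0.8
a1: 0.8
sigma: 0.4
dt: 0.01
days_per_unit: 10.0
obs_scale: 1.9955
obs_offset: -1.6184
state_range: [0.0, 4.0]
missing_rates: [0.0058, 0.0030, 0.0044]
attrition_rates: [0.18, 0.21]
linear:
  c0: 0.5
  c1: 0.75
  c2: 0.0
  c3: 0.0
  noise: 0.3
  distress: {mean: 2.0, sd: 0.55, lo: 0.0, hi: 4.0, loading: 0.9}
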