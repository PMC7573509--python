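# Synthetic condition calibrated to the California-wildfires sample
# descriptives (waves at baseline, 6 weeks, 6 months; n = 148;
# peritraumatic dissociation as the asymmetry source).
n_subjects: 148
study_profile: study2
wave_labels: [T1, T2, T3]
wave_days: [0.0, 42.0, 183.0]
gender_p_female: 0.729
asymmetry_source: pd
covariates:
  cse: {mean: 5.07, sd: 1.22, lo: 1.0, hi: 7.0, loading: -0.65}
  pd: {mean: 2.43, sd: 1.01, lo: 0.0, hi: 5.0, loading: 0.3}
  exposure: {mean: 6.75, sd: 1.79, lo: 0.0, hi: 11.0, loading: 0.5, integer: true}
  time_since: {mean: 287.7, sd: 130.99, lo: 0.0, hi: .inf, loading: -0.22}
b0: 1.2
b1: -0.8
a0: 1.2
a1: 0.8
sigma: 0.9
dt: 0.01
days_per_unit: 10.0
obs_scale: 2.0869
obs_offset: -0.69
state_range: [0.0, 4.0]
missing_rates: [0.0032, 0.0, 0.0012]
attrition_rates: [0.446, 0.195]
linear:
  c0: 0.66
  c1: 0.67
  c2: 0.0
  c3: 0.0
  noise: 0.5
  distress: {mean: 2.0, sd: 0.55, lo: 0.0, hi: 4.0, loading: 0.9}
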