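n_subjects: 5000
seed: 0
age_min: 18.0
age_max: 85.0
p_women: 0.515
lon_range:
- 12.0
- 19.0
lat_range:
- 48.5
- 51.1
settlement_log10_mean: 3.5
settlement_log10_sd: 1.0
settlement_log10_range:
- 2.0
- 6.12
decay_men:
- 9.62
- 2.829
- 0.067
decay_women:
- 10.69
- 2.947
- 0.089
p_partner: 0.65
p_children: 0.35
p_dog: 0.41
p_other_pet: 0.15
p_smoking: 0.28
p_alcohol_high: 0.15
p_fruitveg_rarely: 0.4
outdoor_gamma_shape: 3.0
outdoor_gamma_scale: 4.0
effects:
  longitude: -0.05098
  latitude: 0.09535
  log10_settlement: 0.08
  has_children_0_17: -0.25
  partner: -0.22
  dog_owner: 0.18
  outdoor_hours_week: -0.008
  smoking: 0.25
  alcohol_high: 0.3
  fruitveg_rarely: 0.18
target_msfsc_mean: 3.125
target_msfsc_sd: 1.0844
latent_noise_sd: 0.0
target_bamid_mean: 12.109
target_bamid_sd: 3.141
bamid_skew: 4.0
target_corr_msfsc_bamid: 0.327
p_alarm_free: 0.45
p_wakes_before_given_alarm: 0.2
sdw_mean: 7.1
sdw_sd: 0.6
debt_halfnormal_scale: 0.9
latency_minutes:
- 5
- 30
wd_values:
- 0
- 3
- 4
- 5
- 6
wd_probs:
- 0.08
- 0.07
- 0.15
- 0.6
- 0.1
alertness_halfwidth:
- 1.0
- 4.0
p_free_day: 0.32
p_typical_day: 0.85
diary_mid_noise_sd: 0.3
biomarker_fraction: 0.22
hdl_mean_men: 1.35
hdl_mean_women: 1.75
hdl_sd: 0.32
ldl_mean: 3.0
ldl_sd: 0.8
hdl_shift_extreme_women: -0.1
hdl_shift_late_women: -0.12
bmi_mean_men: 26.5
bmi_mean_women: 25.0
bmi_sd: 4.0
bmi_slope_women: 0.35
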