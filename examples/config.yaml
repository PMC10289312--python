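seed: 0
synth:
  seed: 0
  n_days: 8
  performances_per_day: 13
  ride_time_range:
  - 3.5
  - 6.5
  knee_angle_range:
  - 140.0
  - 180.0
  knee_penalty_rate: 0.01
  judge_noise_sd: 0.05
  flow_noise_sd: 0.15
  straight_leg_threshold_deg: 162.5
  meta:
    fps: 60.0
    width: 160
    height: 120
    n_frames: 1
    motion_direction: leftward
events:
  eps: 0.5
  window: 30
  min_contact_s: 0.5
  lookback: 10
  mag_lo: 0.6
  mag_hi: 4.0
  circular_median: false
side: left
model:
  forest:
    n_estimators: 100
    max_depth: null
    max_features: 1.0
    min_samples_leaf: 1
  importance_threshold: 0.1
  n_test_days: 2
  baseline_feature: time_on_wheel
  baseline_regressor: ols
stats:
  cond_a: time_on_wheel<=4.935
  cond_b: knee_pikemount>162.5
  control_group: I
  alpha: 0.05
  alternative: two-sided
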