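# Study configuration file (YAML)

Every section is optional; omitted sections fall back to the package
defaults (logged at load time). Fields are validated by the pydantic
models in `daindex.config`; unknown keys are rejected.

```yaml
calendar:
  induction_date: 2017-01-09   # study day 0
  study_start_day: -3
  booster_day: 7
  dosing_start_day: 9
  final_day: 17
  baseline_start: -2           # baseline window; day 0 always excluded
  baseline_end: 5

schedule:
  lights_on: "06:00"
  lights_off: "18:00"          # dark (active) cycle 18:00-06:00

thresholds:                    # strict > comparisons
  joint_size_in: 0.25
  arthritis_score: 4
  dai: 5

endpoint:                      # humane-endpoint censoring
  joint_limit_in: 0.4          # inclusive >=
  max_score_days: 3            # consecutive daily observations at score 4
  weight_loss_fraction: 0.20

feature:
  method: q99                  # q99 | max | mean
  scale_k: 20.0
  min_coverage: 0.5
  min_baseline_days: 3

simulation:                    # synthetic-cohort generator
  seed: 0
  n_per_group: 9
  baseline_dark_speed_mean: 22.0
  baseline_dark_speed_sd: 2.4
  within_noise_cv: 0.3
  light_speed_fraction: 0.3
  max_activity_reduction: 0.45
  onset_day_mean: 13.0
  onset_day_sd: 1.0
  endpoint_severity_mean: 0.95
  endpoint_severity_sd: 0.05
  ramp_days: 4.0
  joint_baseline_in: 0.22
  joint_gain_in: 0.12
  joint_noise_in: 0.005
  score_gain: 3.8
  score_noise: 0.3
  histo_noise: 0.4
  weight_baseline_g: 190.0
  weight_loss_max: 0.08
  sample_period_s: 60

groups:                        # simulated experimental arms
  - {name: CIA, n: 9, induced: true}
  - {name: Control, n: 9, induced: false}
  # treated arms: treatment_effect multiplies latent severity
  # (0 = full protection), compound/dose label the arm for ranking
  - {name: DEX-high, n: 9, induced: true, treatment_effect: 0.2,
     compound: dexamethasone, dose: high}
```

## File formats

* `traces.csv` — `animal_id,timestamp,speed_mm_s`; ISO-8601 local
  study time, strictly increasing per animal, speeds finite and >= 0.
* `measurements.csv` — long format `animal_id,study_day,metric,value`
  with metric in `joint_left_in, joint_right_in, paw_score_left,
  paw_score_right, body_weight_g`.
* `histopath.csv` — `animal_id,side,inflammation,pannus,
  cartilage_damage,bone_resorption,periosteal_bone_formation`
  (ordinals 0-5).
* `animals.csv` — `animal_id,group,induced,treatment_effect,compound,dose`.

Pipeline outputs are RFC-4180 CSVs with a leading
`# config_hash=<sha256>` comment line.
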