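# Demo synthetic scenario: one region, stable fertility, natural sex ratio
# at birth, moderate male mortality disadvantage, and a transient male
# conflict-mortality shock.
region_id: DEMO
start_year: 2000
end_year: 2040
srb: 105.0          # male births per 100 female births
tfr: 2.1            # female TFR, births per woman
fertility_schedule:
  mean_age: 28.0
  sd_age: 6.0
mortality:
  gompertz_level: 5.0e-5
  gompertz_slope: 0.1
  sex_gap: 1.4      # male/female hazard ratio
  infant_level: 0.015
  infant_decay: 1.2
shocks:
  - year_start: 2015
    year_end: 2017
    sex: male
    age_start: 18
    age_end: 40
    hazard_multiplier: 3.0
max_age: 100
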