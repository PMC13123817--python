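# Full pipeline run: simulate the demo scenario, fit the age-gap model on a
# synthetic training panel drawn from the shipped reference coefficients,
# estimate male TFRs, standardize, decompose sex ratios, detect crossovers.
scenario: scenario.yaml
out_dir: pipeline_out
variant: age_gap
pi_level: 0.90
pct_threshold: -5.0
standardize_age_range: [15, 55]
training_n: 4000
training_noise_sd: 0.05
seed: 1
log_level: INFO
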