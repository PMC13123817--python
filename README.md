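# maletfr

Tools for studying **sex differences in total fertility rates (TFR)**.
Statistical offices routinely publish the female TFR, but almost never a
male TFR — even though imbalanced sex ratios in the reproductive-age
population can drive the two far apart, and a growing number of populations
have crossed from higher male to higher female fertility. `maletfr` is
aimed at demographers and population scientists working with UN World
Population Prospects (WPP)-style long-format data who want to:

* **estimate male TFRs indirectly** from female TFRs and adult sex ratios,
  with prediction intervals;
* **standardize** the male TFR by applying the observed births by maternal
  age to the male population structure, isolating the pure sex-ratio effect;
* **decompose** age-specific population sex ratios into a birth component
  (sex ratio at birth) and a mortality component (cumulative survivorship
  ratio);
* detect **fertility crossovers** and summarize them across countries; and
* generate fully **synthetic, internally consistent test data** with known
  ground truth via a migration-free cohort-component projection.

## The model

The male TFR is related to the female TFR and the reproductive-age sex
ratio SR (men per woman) through a log-log elasticity regression

```
log TFRm = α + β₁ log TFRw + β₂ log SR + ε
```

fitted by pooled OLS. Three variants differ in the ages defining SR:
`baseline` (men 20–39 / women 20–39), `postponement` (25–44 / 25–44), and
`age_gap` (men 25–44 / women 20–39, reflecting that fathers are typically
older than mothers). With β₁ > 0 > β₂, a masculinizing population (rising
SR) mechanically depresses male fertility relative to female fertility.
A reference coefficient set per variant is shipped in
`maletfr.DEFAULT_COEFFICIENTS` (age-gap: α = −0.078, β₁ = 1.101,
β₂ = −0.661).

The standardized male TFR applies the female birth schedule to the male
age structure over reproductive ages 15–55,

```
TFRstd = Σₓ Bₓ / Pₓᵐ ,
```

and the synthetic-cohort sex ratio at age x decomposes multiplicatively as

```
SRₜ(x) = 100 · (Bₘ/B_w) · Π_{i<x} pₘ(i)/p_w(i)
         └ birth contribution ┘ └ mortality contribution ┘
```

using one year's sex-specific period life tables (empty product at x = 0,
so SRₜ(0) is the sex ratio at birth).

## Worked example

Predict the male TFR with the shipped age-gap coefficients:

```python
>>> from maletfr import DEFAULT_COEFFICIENTS, predict
>>> coefs = DEFAULT_COEFFICIENTS["age_gap"]
>>> round(predict(coefs, tfr_female=2.1, sex_ratio=1.0).point, 2)
2.09
>>> round(predict(coefs, tfr_female=2.1, sex_ratio=2.0).point, 2)
1.32
```

At replacement-level female fertility and a balanced population the model
predicts 2.09 births per man — essentially parity. If men outnumber women
two to one at reproductive ages, the male TFR drops to 1.32: the same
births are spread over twice the male exposure.

Run the full pipeline on the bundled demo scenario (a single region,
2000–2040, SRB 105, female TFR 2.1, moderate male excess mortality, and a
2015–2017 conflict shock tripling male hazards at ages 18–40):

```
$ maletfr run --config examples/pipeline.yaml --out-dir demo_out
...
$ maletfr predict --fit demo_out/fit.json --tfrw 2.1 --sr 1.0
TFRm = 2.09 births per man (90% PI: 1.93 to 2.27)
$ head -3 demo_out/standardized.csv
region_id,year,tfr_std,tfr_female,ratio_std
DEMO,2000,2.0241693336264848,2.0999999999999996,0.9638901588697548
DEMO,2001,2.0241693336264848,2.0999999999999996,0.9638901588697548
```

The standardized male TFR (2.024) sits about 3.6 % below the female TFR
(`ratio_std` ≈ 0.964): with 105 boys born per 100 girls and only a modest
female survival advantage, men outnumber women throughout the reproductive
ages, which deflates per-man fertility. `demo_out/decomposition.csv` splits
the age-specific sex ratio for each year into its birth and mortality
factors, and `demo_out/crossover.csv` / `shares.csv` summarize when and
where male fertility falls below female fertility.

Subcommands (`simulate`, `fit`, `predict`, `estimate`, `standardize`,
`decompose`, `crossover`, `validate`, `run`) all read and write the four
plain CSV schemas documented in `maletfr.core_data`.

### Using WPP data

No parser for the UN's native file layouts is included. To use WPP
extracts, map them to the four CSV schemas: population counts by single age
and sex → `population.csv` (region_id, year, age, sex, count; store the
open-ended "100+" group as age 100); births by sex and single maternal age
→ `births.csv`; survival probabilities from the sex-specific period life
tables → `lifetable.csv`; and the female TFR series → `fertility.csv`.
Births published in 5-year maternal age groups can be split with
`maletfr.split_grouped_births`.

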