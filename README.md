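# cyclodose

Per-cycle internal dosimetry analysis for multi-cycle radionuclide therapy:

- **cohort**: validated domain types and CSV/JSON I/O for per-cycle dosimetry
  tables, including a packaged six-patient, four-cycle reference cohort
  (`cyclodose.ludo_fixture()`).
- **kinetics**: mono-exponential clearance fitting (log-linear OLS on the
  ≥ 24 h washout window) and effective half-life estimation.
- **integration**: hybrid absorbed-dose integration — trapezoid from
  injection (zero-rate anchor) to 24 h plus the analytic mono-exponential
  tail `rate_24h × T_eff / ln 2` — with dose-per-activity derivation and
  left/right kidney averaging.
- **cycle_analysis**: inter-cycle relative differences, cumulative doses,
  per-cycle contribution fractions and cohort median/range summaries.
- **schema_sim**: the fixed dose-per-activity prediction schema
  (`expected = (AD₁/AA₁) × AA_cycle`) and delivered/expected ratio tables.
- **stats**: Wilcoxon–Mann–Whitney (continuity-corrected normal and exact
  enumeration routes), Spearman rank correlation, median/range.
- **synthetic**: seeded cohort simulator with biexponential uptake/clearance
  kinetics, per-cycle tumour-uptake decline, lognormal measurement noise and
  closed-form ground-truth doses for parameter-recovery testing.

## CLI

```sh
cyclodose analyze  --input fixture --out results/   # per-cycle summaries
cyclodose schema   --input fixture --out results/   # delivered vs expected
cyclodose report   --input fixture --out results/   # both + contributions
cyclodose simulate --seed 42 --n-patients 6 --decline 0.7 --out sim/
```

`--input` takes a cohort CSV/JSON path or the literal `fixture`. Each table
is written twice: rounded to 3 significant figures and as `*_full.csv` at
machine precision. A YAML file with option defaults can be passed via
`--config`.

Cohort CSV schema: `patient_id, sex, gfr_ml_min, cycle, aa_gbq, weight_kg,
tumour_ad_gy, kidney_ad_gy, tumour_teff_h, kidney_teff_h` (one row per
patient-cycle). Series CSV schema: `patient_id, cycle, structure, time_h,
rate_gy_per_h`.

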