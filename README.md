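# labri

Indirect reference-interval (RI) estimation for mixed laboratory
populations, with antibody-stratified subgroup comparison.

Routine laboratory data mix non-pathological results with pathological
contamination in both tails. `labri` estimates the central 95% reference
interval of the non-pathological component directly from such mixed data:

1. **Cohort preparation** — exclusion filters (age window, complete hormone
   panel, pregnancy / inpatient / thyroid-treatment flags), per-analyzer
   thyroid-antibody classification (Tg-Ab / TPO-Ab against kit cutoffs),
   stratification into analyzer x sex x antibody-status x analyte subgroups,
   and per-subgroup Tukey outlier filtering (`labri.prep`).
2. **Indirect estimation** — Box-Cox transformation over an exponent grid,
   mode-anchored histogram window expansion with truncated-normal maximum
   likelihood and chi-square goodness-of-fit stopping, back-transformed
   central-95% limits, and 90% percentile-bootstrap confidence intervals
   from 250 replicates with the exponent frozen (`labri.estimate`).
3. **Interval comparison** — bias ratios of both limits,
   `BR = (L - L0) / SD_RI` with `SD_RI = (UL0 - LL0)/3.92`, flagged at
   `|BR| >= 0.375`; Mann-Whitney U group comparison and Shapiro-Wilk
   normality reporting (`labri.compare`).
4. **Synthetic cohorts** — a generative model with per-cell Box-Cox normal
   mixtures (dominant healthy component + low/high tail contamination),
   latent antibody states, and closed-form true limits for recovery testing
   (`labri.synthetic`).
5. **Pipeline + CLI** — one deterministic run from config to CSV/JSON
   reports with a provenance block (`labri.pipeline`, `labri.cli`).

## CLI

```bash
labri simulate --n 20000 --seed 1 --out cohort.csv     # synthetic cohort CSV
labri estimate cohort.csv --seed 1 --out results/      # RI tables from a cohort
labri compare results/intervals.csv --out br.csv       # bias ratios (Ab+ vs Ab-)
labri run --config run_config.json --seed 1 --out out/ # full pipeline
labri fixtures --out fixtures/                         # small toy inputs
```

`labri run` writes `intervals.csv` / `comparisons.csv` / `report.json` /
`table.txt` / `run.log`; re-running the same config and seed reproduces the
files byte-for-byte.

## Data formats

Cohort CSV header (missing values are empty fields):

```
subject_id,age,sex,analyzer,tsh,ft4,ft3,tg_ab,tpo_ab,pregnant,inpatient,thyroid_dx_or_med
```

`sex` is `M`/`F`; `analyzer` one of `Abbott`, `Beckman`, `Roche`, `Siemens`.

Run config (JSON): exactly one of `synthetic` (a cohort generator config —
see `labri fixtures` for a worked example) or `cohort_csv` (path), plus
optional `cutoffs` (per-analyzer `[tg, tpo]`), `age_min`/`age_max`
(default 18–50), `estimator` (lambda_grid, central_coverage 0.95, ci_level
0.90, bootstrap_reps 250, gof_alpha 0.01, min_n 400, ...), `tukey_k` (1.5),
`br_threshold` (0.375), `subgroups`, `comparisons`
(`"analyzer|sex|antibody|analyte"` keys), and `seed`.

Interval tables: `analyzer, sex_stratum, antibody_stratum, analyte, n, LL,
UL, LL_ci_low, LL_ci_high, UL_ci_low, UL_ci_high, lambda_hat`.
Comparison tables: `test_key, ref_key, sd_ri, br_ll, br_ul, sig_ll, sig_ul,
flags` with the `LL* + UL` style star-flag vocabulary.

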