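# tsmr

Two-sample Mendelian randomization (MR) from GWAS summary statistics:
instrument selection and vetting, effect-allele harmonization, causal
estimation (inverse-variance weighted, MR-Egger, weighted median), and a
sensitivity suite (Cochran's Q, Egger intercept, residual-sum-of-squares
outlier testing, leave-one-out), plus a synthetic summary-statistic
generator with known ground truth so every stage is testable offline.

The package ships, as data fixtures, the published instrument tables for
two exposures — benign prostatic hyperplasia (23 SNPs) and prostatitis
(10 SNPs) — together with the cohort metadata, and can reproduce the
published instrument-strength statistics desk-side. The outcome-side
causal estimates need an external prostate-cancer GWAS; see
`docs/external_data.md`.

## Library overview

| module            | contents                                                                  |
|-------------------|---------------------------------------------------------------------------|
| `tsmr.gwas_io`    | `SummaryStatRecord`/`StudyMeta`, TSV read/write with dialect maps, fixtures |
| `tsmr.instruments`| p-value selection, greedy LD clumping, confounder screen, R²/F strength    |
| `tsmr.harmonize`  | allele alignment: swaps, strand flips, palindromic frequency inference     |
| `tsmr.estimators` | Wald ratios, IVW (fixed/multiplicative-random), MR-Egger, weighted median  |
| `tsmr.diagnostics`| Cochran's Q, Egger intercept, RSS outlier/global/distortion tests, LOO,    |
|                   | forest/funnel/scatter plot data                                            |
| `tsmr.synthetic`  | `simulate_two_sample`, `recovery_experiment` (bias/SE/coverage grids)      |
| `tsmr.pipeline`   | `AnalysisConfig` (YAML) and `run_analysis` orchestration                   |

```python
import tsmr

exposure = tsmr.load_fixture("bph_instruments")
selected = tsmr.select_instruments(exposure, p_threshold=5e-6)
fmin, fmax, n_strong = tsmr.strength_summary(selected)

hset = tsmr.harmonize(selected.records, outcome_records)
estimate = tsmr.ivw(hset, model="random")
print(estimate.or_point, estimate.or_ci_low, estimate.or_ci_high)
```

## CLI

```sh
tsmr fixtures --name bph_instruments          # dump a packaged table
tsmr strength exposure.tsv --n 463010         # instrument-strength metrics
tsmr simulate --seed 7 --k 30 --theta 0.1 --out-prefix sim   # synthetic data
tsmr run config.yaml                          # full pipeline from YAML config
```

A minimal config:

```yaml
exposure: bph_instruments   # fixture name or TSV path
outcome: outcome.tsv
p_threshold: 5.0e-6
ld_r2_threshold: 0.001
model: auto_by_q            # random effects when Cochran's Q p < 0.05
seed: 1
out_dir: results/run1
```

`run` writes `report.json` (validated against the shipped schema) plus
TSV side tables (estimates, harmonization, leave-one-out, plot data).
Runs are deterministic given the config and seed; timestamps are
quarantined in one report field.

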