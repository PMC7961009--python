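# mrkit

Two-sample Mendelian randomisation (MR) from GWAS summary statistics.

Observational associations between a modifiable exposure and a disease are
vulnerable to confounding and reverse causation. MR sidesteps both by using
germline variants as instrumental variables: because alleles are randomly
assorted at conception, a variant that raises the exposure provides an
unconfounded handle on the exposure's downstream effect. In the two-sample
design the variant–exposure and variant–outcome associations come from
separate GWAS, so only published summary statistics are needed.

`mrkit` implements the full analysis for one exposure–outcome pair:

* **I/O** — delimited summary-statistic tables (remappable columns) and
  r² LD matrices, with validation and row-level diagnostics
  (`mrkit.sumstats_io`).
* **Instrument construction** — significance (P < 5×10⁻⁸), MAF (> 0.01)
  and imputation-info (≥ 0.8) filters, greedy LD pruning at r² ≥ 0.01
  keeping the strongest effect, and allele harmonisation with outright
  removal of palindromic SNPs (`mrkit.instruments`).
* **Estimators** — per-SNP Wald ratios β̂_Y/β̂_X; multiplicative
  random-effects IVW, θ̂ = Σwβ̂_Xβ̂_Y / Σwβ̂_X² with w = σ_Y⁻² and SE
  inflated by φ̂ = max(1, √(Q/(J−1))); MR-Egger regression (intercept =
  directional pleiotropy, t inference with J−2 df); weighted median and
  weighted mode with parametric-bootstrap SEs (`mrkit.estimators`).
* **Diagnostics** — Cochran's Q and I², funnel/forest data export, and
  MR-PRESSO global, outlier and distortion tests (`mrkit.diagnostics`).
* **Strength & power** — per-SNP PVE = 2p(1−p)β², mean F =
  (PVE/(1−PVE))·(n−k−1)/k with the Staiger–Stock rule, and analytic power
  for a continuous exposure on a case-control outcome
  (`mrkit.strength_power`).
* **Synthetic data** — a seeded generator for two-sample summary
  statistics with known causal effect, configurable pleiotropy (balanced,
  directional, InSIDE-violating), planted allele flips and palindromic
  SNPs, plus a truth ledger (`mrkit.synthetic_data`).
* **Pipeline & CLI** — `run_analysis` orchestrates everything into a
  report bundle of TSV tables; `mrkit run / simulate / power` expose it
  from the shell (`mrkit.pipeline`, `mrkit.cli`).

See `docs/methods.md` for the statistical model, assumptions and numerical
choices.

## Worked example

Two bundled deterministic synthetic studies mirror the two instrument
regimes the design distinguishes. A two-instrument continuous exposure
(instruments explaining 18% of exposure variance in a GWAS of 9464)
against a null case-control outcome:

```python
from mrkit.pipeline import AnalysisConfig, run_analysis
from mrkit.synthetic_data import bilirubin_like_study, write_study

exposure, outcome, ld = bilirubin_like_study()
paths = write_study("demo", exposure, outcome, ld=ld)
bundle = run_analysis(AnalysisConfig(
    exposure_path=paths["exposure"], outcome_path=paths["outcome"],
    ld_path=paths["ld"], seed=1, n_cases=26_397, n_controls=41_481,
))
print(bundle.estimates[["method", "n_snps", "or_point", "or_low", "or_high", "pval"]])
print(bundle.strength)
```

```
 method  n_snps  or_point  or_low  or_high   pval
   WALD       1    1.0036  0.9644   1.0445 0.8582
MRE_IVW       2    1.0011  0.9654   1.0382 0.9514
 pve_total  mean_f  passes_staiger_stock  n_exposure  k
      0.18  1038.4                  True        9464  2
classification: NULL
```

With only two instruments the report contains the Wald and IVW rows only —
MR-Egger, weighted median and weighted mode need at least three
instruments and are marked not applicable. The odds ratio per SD of
exposure is 1.00 (95% CI 0.97–1.04), a null result, while mean F = 1038
says the instruments themselves are very strong, and the power annex shows
this configuration had >99% power to detect an OR_SD of 1.10 (74.8% for
1.05).

The 26-instrument binary-exposure study exercises the full suite; its
outcome effects carry planted heterogeneity including three 10-SE
outliers:

```
 method  n_snps   pval  theta     se  or_point
   WALD       1 0.0000 0.1883 0.0186    1.2072
MRE_IVW      26 0.0000 0.1882 0.0197    1.2071
  EGGER      26 0.0034 0.1906 0.0586    1.2100
    WME      26 0.0000 0.1920 0.0085    1.2116
    WMO      26 0.0000 0.1890 0.0120    1.2080
      q  df  pval     i2
264.798  25   0.0 90.559
 global_pval  n_outliers                   outliers
    0.000999           3 rs000060;rs000130;rs000200
```

Because the exposure is binary, every row carries a caveat flag and the
table is ordered p-value-first: ratio estimates for a binary exposure on a
binary outcome can be inflated in magnitude when a true effect exists, so
the p-value is the primary result and ORs are reported for completeness.
Cochran's Q (I² = 91%) flags the planted heterogeneity and MR-PRESSO
pinpoints exactly the three displaced SNPs.

The same analyses run from the shell:

```bash
mrkit simulate --out-dir sim --seed 7 --n-snps 50 --theta 0.1
mrkit run --exposure sim/exposure.tsv --outcome sim/outcome.tsv \
    --seed 7 --out-dir report
mrkit power --pve 0.18 --n-cases 26397 --n-controls 41481
```

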