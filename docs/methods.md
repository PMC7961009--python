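# Methods

`mrkit` implements a complete two-sample Mendelian randomisation (MR)
analysis over GWAS summary statistics: instrument construction, allele
harmonisation, a suite of causal-effect estimators, heterogeneity and
pleiotropy diagnostics, and instrument-strength / power calculations, plus
a generative model for synthetic summary statistics with known ground
truth. This note records the model, the numerical choices, and what the
synthetic benchmarks do and do not establish.

## Model and assumptions

Per SNP *j*, two independent GWAS supply an exposure association
(β̂<sub>Xj</sub>, σ<sub>Xj</sub>) and an outcome association
(β̂<sub>Yj</sub>, σ<sub>Yj</sub>), aligned to the same effect allele.
Under the instrumental-variable assumptions (variant associated with the
exposure; no variant–outcome confounding; no effect on the outcome except
through the exposure), each Wald ratio β̂<sub>Yj</sub>/β̂<sub>Xj</sub>
estimates the causal effect θ of one exposure unit (SD of a continuous
trait, or log-odds of a binary trait) on the outcome.

Estimators over a harmonised instrument set of size J:

* **MRE-IVW** — weighted regression of β̂<sub>Y</sub> on β̂<sub>X</sub>
  through the origin, weights σ<sub>Y</sub>⁻². The multiplicative
  random-effects scale φ̂ = max(1, √(Q/(J−1))) inflates the fixed-effect SE
  under over-dispersion; the floor at 1 means under-dispersion never
  shrinks it. Valid in the presence of pleiotropy only when direct effects
  are balanced and the InSIDE condition (instrument strength independent of
  direct effect) plus NoME (no measurement error in β̂<sub>X</sub>) hold.
* **MR-Egger** — the same regression with an intercept, after orienting all
  exposure effects non-negative. The intercept estimates the mean
  directional pleiotropic effect; the slope remains consistent for θ under
  InSIDE. Inference is t-based with J−2 df, with the same multiplicative
  scale floor.
* **Weighted median** — the ratio at cumulative weight 0.5 (linear
  interpolation over cumulative-midpoint positions), consistent when valid
  instruments carry ≥ 50% of the weight.
* **Weighted mode** — the argmax of the inverse-variance-weighted
  normal-kernel density of the ratios, consistent when the largest cluster
  of ratios is valid.

Weights use first-order Wald SEs (σ<sub>Yj</sub>/|β̂<sub>Xj</sub>| for
ratios) throughout; exposure-side uncertainty is ignored on the grounds of
instrument strength, which the F statistic makes checkable (the studies
this design targets have mean F in the hundreds to thousands). A
second-order delta-method SE is available on `wald_ratio` but off by
default.

## Diagnostics

**Cochran's Q / I²** measure dispersion of the Wald ratios about their
inverse-variance-weighted mean, with first-order weights (consistent with
the estimator suite; modified second-order weights are a known alternative
we deliberately do not mix in). I² = max(0, (Q−df)/Q)·100.

**MR-PRESSO** uses unweighted squared residuals about leave-one-out
fixed-effect IVW slopes. The global test compares the observed residual sum
of squares with a parametric simulation null (effects redrawn from their
normals, outcome centred on the leave-one-out prediction; leave-one-out
slopes re-fitted per simulated dataset). The outlier test compares each
SNP's residual with its simulated distribution, Bonferroni-multiplied by J,
flagged below 0.05 by default. The distortion test expresses the change of
the IVW estimate after outlier removal as a percentage and compares it with
removing equally many SNPs at random. Empirical p-values carry the
(1+exceedances)/(n_sim+1) correction, so they live in [1/(n_sim+1), 1];
bit-reproducibility follows from the seed. Note the detection resolution:
with J instruments the Bonferroni-adjusted empirical p cannot fall below
J/(n_sim+1), so flagging any outlier at α = 0.05 needs n_sim > J/0.05 − 1
(the default n_sim = 1000 covers J up to 50).

## Instrument construction

Candidates must pass P < 5×10⁻⁸, minor-allele frequency > 0.01 and
imputation info ≥ 0.8 (records missing the info score fail unless
`allow_missing_info` is set; records missing a frequency fail the MAF
filter — a record that cannot demonstrate MAF > 0.01 is not assumed to).
LD pruning is greedy at r² ≥ 0.01: records are visited by decreasing
|β̂|, ties broken by ascending identifier, keeping a SNP iff its r² with
every already-kept SNP is below threshold — so the strongest effect always
survives and the retained set is pairwise independent at the threshold.

Harmonisation takes the exposure records as the reference orientation.
Outcome records with swapped effect/other alleles are negated and
frequency-complemented; pairs resolvable only as strand complements are
complemented first; palindromic (A/T, C/G) SNPs are removed outright with
no frequency-based rescue, and irreconcilable pairs are removed.
Instruments absent from the outcome GWAS are dropped and counted (no proxy
lookup). Every removal is logged to a stage ledger (stage, SNPs in/out,
reasons with counts).

## Strength and power

For a variance-standardised continuous exposure, per-SNP PVE =
2p(1−p)β², summed over independent instruments for the total. Mean F =
(PVE/(1−PVE))·(n−k−1)/k, with the Staiger–Stock rule (F > 10) as the
weak-instrument bar. Power for a continuous exposure against a
case-control outcome uses the normal approximation with non-centrality
|ln OR|·√(N·PVE·v(1−v)) (v the case fraction); two-sided by default, with
a one-sided option, since the sidedness convention differs between
published calculators — at OR = 1 the two-sided version returns exactly α.
Neither strength nor power is defined here for a binary exposure in a
two-sample design; requesting it raises a documented not-supported error
and the pipeline notes the omission instead.

## Synthetic data generator

The generator emulates two-sample summary statistics under a linear
structural model: maf ~ U(maf_range); true β<sub>Xj</sub> ~ N(0,
beta_x_sd²); direct effect α<sub>j</sub> ~ N(pleiotropy_mean,
pleiotropy_sd²); true β<sub>Yj</sub> = θ·β<sub>Xj</sub> +
sign(β<sub>Xj</sub>)·α<sub>j</sub>; SEs follow the standardised-trait GWAS
approximation se = (2p(1−p)n)^(−1/2) with a (v(1−v))^(−1/2) factor for
case-control outcomes; observed effects add N(0, se²) noise.

Two generator choices deserve a note:

* **Pleiotropy is attached to the exposure-increasing allele** (the
  sign(β<sub>X</sub>) factor). Allele orientation is arbitrary, so a
  "directional" shift must be directional *relative to something*; defining
  it in the exposure-increasing frame reproduces the canonical Egger
  generative model exactly. An orientation-free additive α would cancel out
  of IVW whenever the β<sub>X</sub> are sign-symmetric, making directional
  pleiotropy undetectable by construction.
* **InSIDE violation** is a correlation between α and instrument strength
  |β<sub>X</sub>|, implemented through a shared standard-normal latent so
  the target correlation is exact.

Defaults were fixed once as the reference study conditions: J = 50
instruments, both GWAS of 100,000, maf ~ U(0.05, 0.5), beta_x_sd = 0.1 —
which makes the instrument set explain ≈ 18% of exposure variance with
per-SNP F of several hundred, the strong-instrument regime this design
assumes — θ = 0, no pleiotropy, 20% of outcome records emitted with
swapped alleles and 10% of SNPs palindromic to keep harmonisation honest.
A `target_pve` option rescales the true effects to hit a requested total
PVE exactly. Everything derives from a single integer seed, and a truth
ledger records every latent quantity per SNP.

What the generator does **not** model: LD between instruments (they are
pruned to independence in the target design; an optional block LD matrix
exists purely to exercise the pruner), winner's-curse inflation of the
discovery-sample effects, population stratification, and sample overlap
between the two GWAS. Passing the synthetic benchmarks therefore shows the
estimators and diagnostics are implemented correctly under their stated
assumptions, not that those assumptions hold in any particular real
dataset.

Two deterministic example studies (`bilirubin_like_study`,
`gallstone_like_study`) are constructed analytically rather than sampled:
a two-instrument continuous-exposure study whose instruments explain
exactly 18% of exposure variance in a GWAS of 9464 (so the mean F evaluates
to 1038), and a 26-instrument binary-exposure study with planted
heterogeneity including three 10-SE outliers. Both are synthetic; no real
summary statistics are reproduced.

## Pipeline and reporting

`run_analysis` applies filter → (optional) LD-prune → harmonise, then the
estimator suite by instrument count: one instrument yields only its Wald
ratio; two allow IVW; three or more add Egger, weighted median and
weighted mode (with J−2 df, Egger needs at least three); four or more add
MR-PRESSO (each leave-one-out fit then has ≥ 3 SNPs). For J > 1 the Wald
row reports the strongest instrument's ratio, kept for reference. The
primary result is the MRE-IVW p-value (the Wald p for a single
instrument), classified against a Bonferroni-corrected threshold
α = 0.05/(number of exposures in the family; default 2 gives 0.025), with
α < p < 0.05 labelled suggestive. Binary-exposure estimates are flagged
with a caveat and the report is ordered p-value-first with ORs demoted to
trailing columns, because ratio estimates for a binary exposure on a
binary outcome can be inflated in magnitude when a true effect exists.

Stochastic components (bootstrap SEs, PRESSO) draw child seeds as fixed
offsets of the config seed, making the whole report bundle byte-identical
across reruns. The run log stores versions, seed, thresholds and stage
notes; no timestamps, for the same reason.

## Numerical choices and degenerate inputs

* Bootstrap SEs: parametric (effects redrawn from their normals), default
  n_boot = 1000, mandatory caller seed. A degenerate resample set gets a
  relative floor on the SE so confidence intervals stay well-formed.
* Weighted-mode bandwidth: h = φ·0.9·min(weighted SD, 1.4826·weighted
  MAD)·J^(−1/5), φ = 1 by default; density argmax taken on a 4096-point
  grid over the ratio range. All-identical ratios (h = 0) return the
  common value.
* Empirical p-values are floored by the +1 correction; analytic p-values
  are floored at the smallest positive float to respect p ∈ (0, 1].
* Zero exposure effects: rejected as instruments at harmonisation (reason
  "null exposure effect"); `wald_ratio` raises on a zero denominator.
* LD matrices are validated to symmetry within 1e-8, unit diagonal and
  values in [0, 1].

## Benchmark problem sizes

The acceptance suites use 500 replicates at J = 50 for estimator recovery
and IVW coverage, 200 replicates for the directional-pleiotropy
comparison, 200 seeds at n_sim = 300 for PRESSO null calibration
(empirical-p resolution 1/301 is ample at α = 0.05) and n_sim = 1000 for
planted-outlier detection. Monte-Carlo acceptance bands are ±3 MC SEs for
means, [92%, 98%] for nominal-95% coverage, and [1%, 10%] for the 5%-level
null rejection rate. The directional-pleiotropy and PRESSO suites build
instruments through the package's own QC path (significance filter before
harmonisation), matching the design being emulated; this also excludes
sign-uncertain near-null instruments, whose mis-orientation would
otherwise attenuate the Egger intercept at high leverage.

## Known limitations

First-order weights understate uncertainty for weak instruments (checked,
not corrected, via F). The weighted-mode SE is bandwidth-dependent and its
sampling distribution is heavy-tailed when any |β̂<sub>X</sub>| is small.
No support for correlated instruments, proxy SNPs, multivariable or
bidirectional MR, Steiger filtering, or non-linear exposure–outcome
models. Binary-exposure effect magnitudes are reported only with a caveat;
their per-SD interpretation is not attempted.
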