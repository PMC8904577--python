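# pgsabs — polygenic scores on the absolute scale

A polygenic score ranks a person against a reference population, but the
rank alone answers neither of the questions people actually ask: *how likely
am I to develop the disease?* and *what trait value should I expect?*
`pgsabs` answers both from summary statistics only — no individual-level
data are needed.

**Binary phenotypes.** The standardized score Z in the population is a
two-component normal mixture: cases and controls each contribute a normal
with common within-group SD and means separated by Cohen's *d*. Given the
prevalence *K* and one predictive-utility metric (AUC, *d*, OR per SD, or
R² on the observed or liability scale — all interconvertible via
AUC = Φ(d/√2), d = r/√(P(1−P)(1−r²)), d = ln(OR)·√3/π and the Lee et al.
liability transformation), standardization pins the mixture to mean 0 and
variance 1, which fixes everything in closed form:

    σ_w = 1/√(1 + K(1−K)d²),   μ_ctrl = −K·d·σ_w,   μ_case = (1−K)·d·σ_w

Mixture quantiles come from bracketed Brent root-finding on the mixture
CDF, and the case probability inside a quantile is Bayes' rule:
P(case | a < Z ≤ b) = K·(Φ_case(b) − Φ_case(a)) / (F(b) − F(a)).

**Continuous phenotypes.** Score and trait are bivariate normal with
ρ = √R². The trait mean and SD inside a score quantile follow from the
truncated standard-normal moments m, v of the quantile interval:

    E[Y | Z ∈ (a,b]] = μ + ρσ·m,     Var[Y | Z ∈ (a,b]] = σ²(1−ρ²) + ρ²σ²·v

with prediction intervals from the conditional SD.

A simulation module draws cohorts with exactly this structure and re-runs
the observed-vs-estimated comparison per score quantile, so the whole chain
is testable end to end.

## Worked examples

Schizophrenia: prevalence 1%, score AUC 0.67, an individual at Z = 1.96:

```bash
$ pgsabs binary --prevalence 0.01 --auc 0.67 --z 1.96
{
  "z": 1.96,
  "percentile": 97.49349199370656,
  "quantile_index": 974,
  "n_quantiles": 1000,
  "case_probability": 0.027447537821755113,
  "case_probability_pct": 2.7
}
```

The individual sits at the 97.5th percentile of scores, yet their absolute
risk is only 2.7% — the mixture components overlap heavily at this AUC, so
an impressive rank translates into a modest risk above the 1% baseline.

IQ: population mean 100, SD 15, a score explaining 10% of variance, an
individual at Z = −1.96:

```bash
$ pgsabs continuous --mean 100 --sd 15 --r2 0.10 --z -1.96
{
  "z": -1.96,
  "percentile": 2.4997895148220435,
  ...
  "predicted_mean": 90.6620319691854,
  "predicted_sd": 14.23026942562626,
  "prediction_interval": [62.77121640465646, 118.55284753371436]
}
```

Expected IQ 90.7 — about 9 points below the mean — but the 95% prediction
interval (62.8, 118.6) spans most of the population range, because 90% of
the trait variance is unexplained by the score.

Other subcommands: `pgsabs convert` (metric arithmetic), `pgsabs validate`
(simulate a cohort under the model and compare observed vs estimated
per-quantile values), `pgsabs standardize` (raw scores → Z-scores against a
reference mean/SD). Batch input is a plain TSV (`IID`, `SCORE`) or a
PLINK2 `.sscore` file; `--plot` renders per-quantile charts.

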