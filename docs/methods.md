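# Methods

## Model for binary phenotypes

Let Z be a polygenic score standardized to the population (mean 0, SD 1).
Cases and controls are assumed to have normally distributed scores with a
common within-group SD σ_w and a standardized mean difference d (Cohen's
d). With prevalence K, the marginal distribution of Z is the mixture
K·N(μ_case, σ_w²) + (1−K)·N(μ_ctrl, σ_w²), and requiring mixture mean 0 and
variance 1 gives the closed-form parameters shown in the README. The
equal-variance assumption is what makes AUC = Φ(d/√2) exact; it is a
modelling choice, not a theorem, and scores with strongly unequal
case/control variances (e.g. very sparse variant sets) will deviate.

Quantile boundaries of the mixture are found with Brent's method bracketed
on [μ_min − 10σ_w − 10, μ_max + 10σ_w + 10] at absolute tolerance 1e-10;
the bracket cannot fail for any quantile with |Φ⁻¹(q)| ≤ 8, and failure
raises a diagnostic error carrying the bracket and tolerance rather than
returning a bad root. The CDF is evaluated through `scipy.special.ndtr`
(the root-finder calls it thousands of times per table; the low-overhead
entry point keeps a 1000-quantile table under ~100 ms on one core).

Per-quantile case probability is Bayes' rule on the component masses. Two
conservation laws are enforced by tests rather than construction: the
unweighted mean of per-quantile probabilities equals K (total probability
over equal-mass cells), and risk is non-decreasing in quantile whenever
d > 0.

An individual's percentile is reported from the **mixture** CDF, which is
exact under the model. For realistic d the mixture CDF and the standard
normal CDF agree to the first decimal of a percentile (97.5 at z = 1.96
either way); the choice only matters for very discriminative scores.

## Model for continuous phenotypes

(Z, Y) is bivariate normal with correlation ρ = +√R², trait mean μ and SD
σ in trait units. The score axis is partitioned by standard-normal
quantiles (the marginal of Z is exactly N(0,1) here — no root-finding
needed), and conditional trait moments per cell follow from the truncated
standard-normal moments, computed by the exact closed form in φ and Φ with
the one-sided limits used for the two tail cells; infinite boundaries are
never clipped. The closed form is cross-checked in the tests against
`scipy.stats.truncnorm` and against rejection sampling, two routes
independent of the implementation.

Orientation: ρ = +√R² assumes higher score → higher trait value. A
`--negative-orientation` flag (rho = −√R²) covers scores oriented the other
way; nothing else changes.

Prediction intervals default to the within-cell conditional SD at the
individual's cell of a 1000-cell partition. The point-conditional SD
σ√(1−ρ²) is exposed as an option (`--point-conditional`); at 1000 cells
the two differ by less than 0.01 trait-SD everywhere and are
indistinguishable at display precision. Intervals are symmetric normal
intervals: mean ± Φ⁻¹((1+level)/2)·SD.

Discretization: at 1000 cells the per-cell conditional mean tracks the
point-conditional mean at the cell's probability midpoint to within 0.1%
of σ for |z| ≤ 2.5; the outermost cells inside |z| ≤ 3 widen enough that
the deviation grows to ~0.2% of σ. Both bounds are asserted in the tests;
at the worked-example z = −1.96 the discretization error is ~10⁻⁴ σ.

Stratified use (e.g. height by sex) is pure re-parameterization with
stratum-specific (μ, σ, R²); the tests assert the code path is identical.

## Metric conversions

All binary-outcome metrics route through Cohen's d:

| metric | relation | needs |
|---|---|---|
| AUC | d = √2·Φ⁻¹(AUC) | — |
| point-biserial r | d = r/√(P(1−P)(1−r²)) | case fraction P |
| OR per SD | d = ln(OR)·√3/π | — |
| R² (observed) | r = √R², then as above | P |
| R² (liability) | Lee et al. (2012) inverse, then as above | K and P |

The r↔d form is the standard sampling-ratio-aware point-biserial
inversion; the OR conversion uses the logistic latent-scale constant
π/√3 ≈ 1.8138. Both are deliberately isolated in `effect_metrics` so they
can be swapped without touching the mixture machinery if a different
convention is preferred. The Lee transformation implements the full
ascertainment-aware form R²_l = C·R²_o/(1 + C·θ·R²_o) with
C = K(1−K)/φ(T)² · K(1−K)/(P(1−P)) and θ the ascertainment term, which
vanishes at P = K. Scores must be oriented so higher score ⇒ higher risk:
AUC < 0.5 and OR < 1 are rejected with an instruction to flip, rather than
silently reflected.

## Synthetic cohorts and validation

`simulate_binary_cohort` draws case status at prevalence K and then the
score from that status's mixture component — the exact generative model
the conversion assumes. A liability mode (genetic liability + environmental
noise, thresholded at Φ⁻¹(1−K)) is provided as a robustness check; under
the model the two routes agree, and the liability route exercises the
assumption rather than encoding it. `simulate_continuous_cohort` draws
(Z, Y) jointly bivariate normal. Both are deterministic given a seed
(`numpy.random.default_rng`).

`validate_*` re-runs the observed-vs-estimated comparison: individuals are
split into empirical score quantiles (equal-count bins), the observed case
proportion or trait mean/SD per bin is compared with the model table
parameterized by the cohort's *observed* AUC/R² (Mann–Whitney estimator /
squared sample correlation), and the discrepancy is summarized as a mean
absolute difference: in absolute percentage points of case probability for
binary traits, and as a percentage of the population mean (means) or SD
(SDs) for continuous traits. The continuous convention assumes a trait
mean well away from zero (true for IQ-like or height-like scales); for
near-zero means the relative statistic is not meaningful. Skewness is the
standardized third central moment; it is reported because trait skew is
the main real-world violation of the bivariate-normal assumption.

Because the generator matches the model, these validations demonstrate
**calibration and internal consistency, not real-world accuracy**: they
show the discrepancy is pure sampling noise (it shrinks as n grows) and
that the estimates are exactly right when the assumptions hold. What they
cannot show is robustness to non-normal scores, unequal case/control
variances, skewed traits, age-varying risk, or a mis-stated input metric.
The last failure mode is probed directly: parameterizing the conversion
with an AUC above the cohort's true AUC inflates the estimated top-quantile
risk relative to the observed one (estimated/observed ratio > 1), the
characteristic signature of over-optimistic input metrics.

Default problem sizes: validation cohorts of 5×10⁴ individuals with 20
quantiles (the scale at which per-quantile mean absolute differences for a
balanced common-disease cohort land around 1–2 percentage points, i.e.
per-bin binomial noise at ~2500 individuals per bin), with larger cohorts
(up to 10⁶–10⁷ draws) in the Monte-Carlo oracle tests.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `n_quantiles` | 1000 (individual lookup), 20 (tables/plots) | partition resolution; 1000 makes discretization invisible at display precision, 20 matches typical validation figures |
| `level` | 0.95 | prediction-interval coverage |
| `conditional` | `"cell"` | condition on the quantile cell vs the exact score |
| boundary ties | lower cell | cells are half-open (b_{i−1}, b_i] |

## Known limitations

Lifetime risk only — no age/competing-risk adjustment; the binary model is
not suitable for time-varying hazards. Continuous traits must be
approximately normal; transform skewed traits first or expect SD
miscalibration of the kind the skewness statistic flags. All outputs are
conditional on the correctness of the supplied prevalence and
predictive-utility metric for the target population and ancestry; the
conversions propagate, and the misspecification check quantifies, but
cannot correct, errors in these inputs.
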