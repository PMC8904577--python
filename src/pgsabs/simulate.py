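"""Synthetic cohorts and observed-vs-estimated validation of the conversions.

The conversions in :mod:`pgsabs.binary` and :mod:`pgsabs.continuous` assume
a specific joint distribution of score and phenotype.  This module draws
individual-level cohorts with exactly that structure and then runs the same
comparison a real validation cohort supports: split individuals into
empirical score quantiles, compare the observed case proportion (or trait
mean and SD) per quantile against the model's estimates, and summarize the
discrepancy as a mean absolute difference.  Because the generator matches
the model, the discrepancy is pure sampling noise and must shrink as the
cohort grows — the property the validation tests assert.

Binary cohorts are drawn directly from the mixture (draw case status at
prevalence K, then the score from that status's component).  A liability
mode is also provided, drawing a genetic liability plus environmental noise
and thresholding; under the model the two are equivalent, and the liability
route serves as a robustness check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, norm, skew

from pgsabs.binary import BinaryTraitModel, build_binary_model, risk_by_quantile
from pgsabs.continuous import ContinuousTraitModel, trait_by_quantile
from pgsabs.effect_metrics import auc_to_d, d_to_r, r2_observed_to_liability
from pgsabs.errors import DomainError

__all__ = [
    "SimulatedBinaryCohort",
    "SimulatedContinuousCohort",
    "ValidationSummary",
    "simulate_binary_cohort",
    "simulate_continuous_cohort",
    "observed_auc",
    "observed_r2",
    "validate_binary",
    "validate_continuous",
]


@dataclass(frozen=True)
class SimulatedBinaryCohort:
    """Individual-level case/control cohort drawn from the mixture model."""

    n: int
    case_status: np.ndarray = field(repr=False)
    pgs_z: np.ndarray = field(repr=False)
    true_K: float = 0.0
    true_d: float = 0.0
    seed: int = 0
    mode: str = "mixture"


@dataclass(frozen=True)
class SimulatedContinuousCohort:
    """Individual-level cohort with jointly bivariate-normal score and trait."""

    n: int
    trait_value: np.ndarray = field(repr=False)
    pgs_z: np.ndarray = field(repr=False)
    true_mean: float = 0.0
    true_sd: float = 1.0
    true_r2: float = 0.0
    seed: int = 0


@dataclass(frozen=True)
class ValidationSummary:
    """Observed-vs-estimated comparison across empirical score quantiles.

    ``mean_abs_diff`` is the mean over quantiles of |observed - estimated|:
    for binary cohorts, of the case probability, in absolute percentage
    points; for continuous cohorts, of the trait mean, as a percentage of
    the population trait mean.  ``mean_abs_diff_sd`` (continuous only) is
    the analogous statistic for the trait SD, as a percentage of the
    population SD.
    """

    n_quantiles: int
    per_quantile: pd.DataFrame = field(repr=False)
    mean_abs_diff: float = 0.0
    mean_abs_diff_sd: float | None = None
    observed_auc: float | None = None
    observed_r2: float | None = None
    trait_skewness: float | None = None

    def top_quantile_ratio(self) -> float:
        """Estimated / observed value in the top score quantile."""
        est = self.per_quantile["estimated"].iloc[-1]
        obs = self.per_quantile["observed"].iloc[-1]
        return float(est / obs)


def simulate_binary_cohort(
    K: float, auc: float, n: int, seed: int, mode: str = "mixture"
) -> SimulatedBinaryCohort:
    """Draw a cohort of ``n`` individuals with case prevalence K and score AUC.

    ``mode="mixture"`` samples status then score from the corresponding
    mixture component.  ``mode="liability"`` samples a genetic liability
    explaining the matching liability-scale R², adds environmental noise,
    and thresholds at Phi^{-1}(1-K); the polygenic Z-score is the
    standardized genetic component.
    """
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n}")
    d = auc_to_d(auc)
    model = build_binary_model(K, d)
    rng = np.random.default_rng(seed)

    if mode == "mixture":
        status = rng.random(n) < K
        mu = np.where(status, model.mu_case, model.mu_control)
        z = mu + model.sigma_within * rng.standard_normal(n)
    elif mode == "liability":
        r = d_to_r(d, K)
        r2_liab = r2_observed_to_liability(r * r, K, K)
        g = rng.standard_normal(n) * math.sqrt(r2_liab)
        e = rng.standard_normal(n) * math.sqrt(1.0 - r2_liab)
        status = (g + e) > norm.ppf(1.0 - K)
        z = g / math.sqrt(r2_liab) if r2_liab > 0 else rng.standard_normal(n)
    else:
        raise DomainError(f"mode must be 'mixture' or 'liability', got {mode!r}")

    return SimulatedBinaryCohort(
        n=n, case_status=status.astype(bool), pgs_z=z, true_K=K, true_d=d, seed=seed, mode=mode
    )


def simulate_continuous_cohort(
    mean: float, sd: float, r2: float, n: int, seed: int
) -> SimulatedContinuousCohort:
    """Draw ``n`` individuals with bivariate-normal (score, trait), corr sqrt(r2)."""
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n}")
    model = ContinuousTraitModel(trait_mean=mean, trait_sd=sd, r2=r2)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    noise = rng.standard_normal(n)
    trait = mean + sd * (model.rho * z + math.sqrt(1.0 - r2) * noise)
    return SimulatedContinuousCohort(
        n=n, trait_value=trait, pgs_z=z, true_mean=mean, true_sd=sd, true_r2=r2, seed=seed
    )


def observed_auc(cohort: SimulatedBinaryCohort) -> float:
    """Mann-Whitney AUC of the score: P(random case outscores random control)."""
    cases = cohort.pgs_z[cohort.case_status]
    controls = cohort.pgs_z[~cohort.case_status]
    if len(cases) == 0 or len(controls) == 0:
        raise DomainError("AUC requires both cases and controls in the cohort")
    u, _ = mannwhitneyu(cases, controls, alternative="two-sided")
    return float(u) / (len(cases) * len(controls))


def observed_r2(cohort: SimulatedContinuousCohort) -> float:
    """Squared sample correlation between score and trait."""
    r = np.corrcoef(cohort.pgs_z, cohort.trait_value)[0, 1]
    return float(r * r)


def _empirical_quantile_bins(scores: np.ndarray, n_quantiles: int) -> np.ndarray:
    bins = pd.qcut(scores, n_quantiles, labels=False, duplicates="raise")
    counts = np.bincount(bins, minlength=n_quantiles)
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        raise DomainError(
            f"quantile {empty[0] + 1} of {n_quantiles} contains no individuals; "
            "use a larger cohort or fewer quantiles"
        )
    return bins


def validate_binary(
    cohort: SimulatedBinaryCohort,
    n_quantiles: int = 20,
    auc_source: str = "observed",
    auc_override: float | None = None,
) -> ValidationSummary:
    """Compare observed vs estimated case probability across score quantiles.

    ``auc_source`` selects which AUC parameterizes the estimated table:
    ``"observed"`` (Mann-Whitney AUC of this cohort, the fair comparison),
    ``"true"`` (the generating AUC), or ``"override"`` with
    ``auc_override`` — useful to study how a misstated AUC distorts the
    estimates, which inflates the top-quantile estimated risk.
    """
    if auc_source == "observed":
        auc = observed_auc(cohort)
    elif auc_source == "true":
        auc = float(norm.cdf(cohort.true_d / math.sqrt(2.0)))
    elif auc_source == "override":
        if auc_override is None:
            raise DomainError("auc_source='override' requires auc_override")
        auc = auc_override
    else:
        raise DomainError(f"unknown auc_source {auc_source!r}")

    K_obs = float(np.mean(cohort.case_status))
    model = build_binary_model(K_obs, auc_to_d(auc))
    est = risk_by_quantile(model, n_quantiles).case_probability

    bins = _empirical_quantile_bins(cohort.pgs_z, n_quantiles)
    obs = np.array(
        [float(np.mean(cohort.case_status[bins == i])) for i in range(n_quantiles)]
    )
    per_quantile = pd.DataFrame(
        {"quantile": np.arange(1, n_quantiles + 1), "observed": obs, "estimated": est}
    )
    mean_abs_diff = 100.0 * float(np.mean(np.abs(obs - est)))
    return ValidationSummary(
        n_quantiles=n_quantiles,
        per_quantile=per_quantile,
        mean_abs_diff=mean_abs_diff,
        observed_auc=observed_auc(cohort),
    )


def validate_continuous(
    cohort: SimulatedContinuousCohort, n_quantiles: int = 20
) -> ValidationSummary:
    """Compare observed vs estimated trait mean and SD across score quantiles.

    Differences of means are reported as a percentage of the population
    trait mean, of SDs as a percentage of the population SD.  The cohort's
    trait skewness (standardized third central moment) is included because
    skew in a real trait violates the bivariate-normal assumption and
    degrades the SD agreement.
    """
    r2_obs = observed_r2(cohort)
    obs_mean_pop = float(np.mean(cohort.trait_value))
    obs_sd_pop = float(np.std(cohort.trait_value, ddof=1))
    model = ContinuousTraitModel(trait_mean=obs_mean_pop, trait_sd=obs_sd_pop, r2=r2_obs)
    table = trait_by_quantile(model, n_quantiles)

    bins = _empirical_quantile_bins(cohort.pgs_z, n_quantiles)
    obs_mean = np.array(
        [float(np.mean(cohort.trait_value[bins == i])) for i in range(n_quantiles)]
    )
    obs_sd = np.array(
        [float(np.std(cohort.trait_value[bins == i], ddof=1)) for i in range(n_quantiles)]
    )
    per_quantile = pd.DataFrame(
        {
            "quantile": np.arange(1, n_quantiles + 1),
            "observed": obs_mean,
            "estimated": table.trait_mean,
            "observed_sd": obs_sd,
            "estimated_sd": table.trait_sd,
        }
    )
    mad_mean = 100.0 * float(np.mean(np.abs(obs_mean - table.trait_mean))) / abs(obs_mean_pop)
    mad_sd = 100.0 * float(np.mean(np.abs(obs_sd - table.trait_sd))) / obs_sd_pop
    return ValidationSummary(
        n_quantiles=n_quantiles,
        per_quantile=per_quantile,
        mean_abs_diff=mad_mean,
        mean_abs_diff_sd=mad_sd,
        observed_r2=r2_obs,
        trait_skewness=float(skew(cohort.trait_value)),
    )
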