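"""Absolute case probability from a polygenic score for a binary phenotype.

In a population where a disease has lifetime prevalence K, the standardized
polygenic score is modelled as a two-component normal mixture: cases and
controls each have normally distributed scores with a common within-group
SD and means separated by Cohen's d.  Standardizing against the population
reference pins the mixture to mean 0 and variance 1, which fixes all
component parameters in closed form:

    sigma_within = 1 / sqrt(1 + K(1-K) d²)
    mu_control   = -K d sigma_within
    mu_case      = (1-K) d sigma_within

Quantiles of the mixture have no closed form and are located by bracketed
root-finding on the mixture CDF.  The probability of being a case given a
score in an interval follows from Bayes' rule:

    P(case | a < Z <= b) = K (Phi_case(b) - Phi_case(a)) / (F(b) - F(a))

where F is the mixture CDF.  Over the whole line this recovers K exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr

from pgsabs.errors import DegenerateIntervalError, DomainError, SolverError
from pgsabs.partition import QuantilePartition

__all__ = [
    "BinaryTraitModel",
    "AbsoluteRiskTable",
    "IndividualRiskResult",
    "build_binary_model",
    "mixture_cdf",
    "mixture_pdf",
    "mixture_quantile",
    "quantile_partition",
    "case_probability_interval",
    "risk_by_quantile",
    "individual_risk",
]

_QUANTILE_TOL = 1e-10


@dataclass(frozen=True)
class BinaryTraitModel:
    """Two-component normal mixture for a standardized disease polygenic score.

    Attributes
    ----------
    prevalence
        Population prevalence K of the phenotype.
    cohens_d
        Standardized case-control score separation.
    mu_case, mu_control
        Component means; satisfy K·mu_case + (1-K)·mu_control = 0.
    sigma_within
        Common within-group SD; mixture variance is exactly 1.
    """

    prevalence: float
    cohens_d: float
    mu_case: float
    mu_control: float
    sigma_within: float

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise DomainError(f"prevalence must lie in (0, 1), got {self.prevalence}")
        if self.cohens_d < 0:
            raise DomainError(f"cohens_d must be >= 0, got {self.cohens_d}")
        if self.sigma_within <= 0:
            raise DomainError(f"sigma_within must be > 0, got {self.sigma_within}")


def build_binary_model(K: float, d: float) -> BinaryTraitModel:
    """Construct the standardized case/control mixture from prevalence and d.

    The returned model has mixture mean 0 and variance 1 exactly, matching
    a score standardized against a population reference.
    """
    if not 0.0 < K < 1.0:
        raise DomainError(f"prevalence must lie in (0, 1), got {K}")
    if d < 0:
        raise DomainError(f"cohens_d must be >= 0, got {d}")
    sigma_within = 1.0 / math.sqrt(1.0 + K * (1.0 - K) * d * d)
    mu_control = -K * d * sigma_within
    mu_case = (1.0 - K) * d * sigma_within
    return BinaryTraitModel(
        prevalence=K,
        cohens_d=d,
        mu_case=mu_case,
        mu_control=mu_control,
        sigma_within=sigma_within,
    )


def mixture_cdf(model: BinaryTraitModel, x):
    """Marginal CDF of the score: K·Phi_case(x) + (1-K)·Phi_control(x)."""
    # ndtr instead of norm.cdf: called thousands of times by the root-finder
    K = model.prevalence
    s = model.sigma_within
    return K * ndtr((x - model.mu_case) / s) + (1.0 - K) * ndtr((x - model.mu_control) / s)


def mixture_pdf(model: BinaryTraitModel, x):
    """Marginal density of the score."""
    K = model.prevalence
    s = model.sigma_within
    c = 1.0 / (s * math.sqrt(2.0 * math.pi))
    x = np.asarray(x, dtype=float)
    pc = c * np.exp(-0.5 * ((x - model.mu_case) / s) ** 2)
    p0 = c * np.exp(-0.5 * ((x - model.mu_control) / s) ** 2)
    return K * pc + (1.0 - K) * p0


def mixture_quantile(model: BinaryTraitModel, q: float) -> float:
    """Invert the mixture CDF by bracketed Brent root-finding.

    The bracket spans [mu_min - 10·sigma, mu_max + 10·sigma], comfortably
    containing every quantile with |Phi^{-1}(q)| <= 8.
    """
    if not 0.0 < q < 1.0:
        raise DomainError(f"quantile level must lie in (0, 1), got {q}")
    lo = min(model.mu_control, model.mu_case) - 10.0 * model.sigma_within - 10.0
    hi = max(model.mu_control, model.mu_case) + 10.0 * model.sigma_within + 10.0
    try:
        return float(brentq(lambda x: mixture_cdf(model, x) - q, lo, hi, xtol=_QUANTILE_TOL))
    except ValueError as exc:  # pragma: no cover - bracket failure is defensive
        raise SolverError(
            f"mixture quantile solver failed for q={q}: {exc}",
            bracket=(lo, hi),
            tol=_QUANTILE_TOL,
        ) from exc


def quantile_partition(model: BinaryTraitModel, n_quantiles: int) -> QuantilePartition:
    """Split the mixture into ``n_quantiles`` equal-mass cells."""
    if n_quantiles < 2:
        raise DomainError(f"n_quantiles must be >= 2, got {n_quantiles}")
    b = np.empty(n_quantiles + 1)
    b[0], b[-1] = -np.inf, np.inf
    for i in range(1, n_quantiles):
        b[i] = mixture_quantile(model, i / n_quantiles)
    return QuantilePartition(n_quantiles=n_quantiles, boundaries=b)


def _component_mass(mu: float, sigma: float, a: float, b: float) -> float:
    return float(ndtr((b - mu) / sigma) - ndtr((a - mu) / sigma))


def case_probability_interval(model: BinaryTraitModel, a: float, b: float) -> float:
    """Probability of being a case given a score in (a, b], by Bayes' rule."""
    if not a < b:
        raise DomainError(f"interval bounds must satisfy a < b, got ({a}, {b})")
    K = model.prevalence
    mass_case = _component_mass(model.mu_case, model.sigma_within, a, b)
    mass_control = _component_mass(model.mu_control, model.sigma_within, a, b)
    total = K * mass_case + (1.0 - K) * mass_control
    if total <= 0.0:
        raise DegenerateIntervalError(
            f"interval ({a}, {b}] carries no mixture probability mass"
        )
    return K * mass_case / total


@dataclass(frozen=True)
class AbsoluteRiskTable:
    """Per-quantile case probabilities for a binary-trait mixture model."""

    model: BinaryTraitModel
    partition: QuantilePartition
    case_probability: np.ndarray = field(repr=False)

    def to_frame(self):
        """Tidy table: quantile (1-based), lower, upper, case_probability."""
        import pandas as pd

        b = self.partition.boundaries
        return pd.DataFrame(
            {
                "quantile": np.arange(1, self.partition.n_quantiles + 1),
                "lower": b[:-1],
                "upper": b[1:],
                "case_probability": self.case_probability,
            }
        )


def risk_by_quantile(model: BinaryTraitModel, n_quantiles: int) -> AbsoluteRiskTable:
    """Case probability within each of ``n_quantiles`` equal-mass score cells.

    The equal-mass construction makes the unweighted mean of the per-cell
    probabilities equal the prevalence (total probability), a conservation
    law used as a correctness check.
    """
    part = quantile_partition(model, n_quantiles)
    probs = np.array(
        [
            case_probability_interval(model, *part.cell_bounds(i))
            for i in range(n_quantiles)
        ]
    )
    return AbsoluteRiskTable(model=model, partition=part, case_probability=probs)


@dataclass(frozen=True)
class IndividualRiskResult:
    """Absolute risk for one individual's polygenic Z-score."""

    z: float
    percentile: float
    quantile_index: int
    n_quantiles: int
    case_probability: float


def individual_risk(
    model: BinaryTraitModel, z: float, n_quantiles: int = 1000
) -> IndividualRiskResult:
    """Absolute case probability for an individual with standardized score ``z``.

    The score axis is partitioned into ``n_quantiles`` equal-mass cells
    (default 1000 for precision) and the Bayes case probability of the cell
    containing ``z`` is reported, together with the individual's population
    percentile 100·F(z) under the mixture CDF.
    """
    if not np.isfinite(z):
        raise DomainError(f"z must be finite, got {z}")
    table = risk_by_quantile(model, n_quantiles)
    idx = table.partition.cell_of(z)
    return IndividualRiskResult(
        z=float(z),
        percentile=100.0 * float(mixture_cdf(model, z)),
        quantile_index=idx,
        n_quantiles=n_quantiles,
        case_probability=float(table.case_probability[idx]),
    )
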