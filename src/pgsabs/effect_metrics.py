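"""Conversions among polygenic-score predictive-utility metrics.

Effect-size databases report the discriminative ability of a polygenic
score for a binary outcome in several interchangeable currencies: AUC,
Cohen's d, the point-biserial correlation r, the odds ratio per score SD,
and R² on the observed or liability scale.  Under the equal-variance
binormal / liability-threshold model these are deterministic functions of
one another, so every converter here routes through Cohen's d — the
standardized case-control mean difference — which is the parameter the
mixture model in :mod:`pgsabs.binary` consumes.

Key relations (Phi is the standard normal CDF, phi its density):

* AUC = Phi(d / sqrt(2))                      (binormal, equal variances)
* d   = r / sqrt(P(1-P)(1-r²))                (point-biserial inversion at
                                               case fraction P)
* d   = ln(OR per SD) · sqrt(3)/pi            (logistic-scale latent SD)
* liability R² from observed R² via the Lee et al. (2012) transformation
  with threshold T = Phi^{-1}(1-K).

All converters are pure scalar functions; callers vectorize externally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

from pgsabs.errors import DomainError, MissingContextError

__all__ = [
    "MetricValue",
    "auc_to_d",
    "d_to_auc",
    "r_to_d",
    "d_to_r",
    "or_per_sd_to_d",
    "d_to_or_per_sd",
    "r2_observed_to_liability",
    "r2_liability_to_observed",
    "any_metric_to_d",
    "SUPPORTED_METRICS",
]

#: logistic latent-scale standard deviation ratio, pi/sqrt(3)
_LOGISTIC_SD = math.pi / math.sqrt(3.0)

SUPPORTED_METRICS = (
    "auc",
    "cohens_d",
    "correlation",
    "or_per_sd",
    "r2_observed",
    "r2_liability",
    "r2_continuous",
)


@dataclass(frozen=True)
class MetricValue:
    """One predictive-utility metric with the context its conversion needs.

    Parameters
    ----------
    metric_name
        One of ``auc``, ``cohens_d``, ``correlation``, ``or_per_sd``,
        ``r2_observed``, ``r2_liability``, ``r2_continuous``.
    value
        The metric's numeric value.
    prevalence
        Population prevalence K in (0, 1).  Required for the liability-scale
        R² conversion.
    case_fraction
        Case fraction P in (0, 1) of the sample the metric was estimated in
        (the GWAS sampling ratio).  Required for correlation and observed-R²
        conversions; defaults to the prevalence when only K is given.
    """

    metric_name: str
    value: float
    prevalence: float | None = None
    case_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.metric_name not in SUPPORTED_METRICS:
            raise DomainError(
                f"unsupported metric {self.metric_name!r}; "
                f"expected one of {SUPPORTED_METRICS}"
            )
        for name, v in (("prevalence", self.prevalence), ("case_fraction", self.case_fraction)):
            if v is not None and not 0.0 < v < 1.0:
                raise DomainError(f"{name} must lie in (0, 1), got {v}")


def auc_to_d(auc: float) -> float:
    """Cohen's d from the AUC under the equal-variance binormal model.

    d = sqrt(2) * Phi^{-1}(AUC).  An AUC of 0.5 (no discrimination) maps to
    d = 0; AUC below 0.5 means the score is oriented the wrong way round.
    """
    if not 0.5 <= auc < 1.0:
        raise DomainError(
            f"auc must lie in [0.5, 1), got {auc}; if your AUC is below 0.5, "
            "flip the score orientation (higher score => higher risk) first"
        )
    return math.sqrt(2.0) * float(norm.ppf(auc))


def d_to_auc(d: float) -> float:
    """AUC from Cohen's d: AUC = Phi(d / sqrt(2)). Exact inverse of auc_to_d."""
    if d < 0:
        raise DomainError(f"cohens_d must be >= 0, got {d}")
    return float(norm.cdf(d / math.sqrt(2.0)))


def r_to_d(r: float, case_fraction: float) -> float:
    """Cohen's d from the point-biserial correlation at a given case fraction.

    d = r / sqrt(P(1-P)(1-r²)), where P is the proportion of cases in the
    sample the correlation was estimated in.  The same correlation implies a
    larger separation when the sample is unbalanced, because sqrt(P(1-P))
    is maximal at P = 0.5.
    """
    if not 0.0 <= r < 1.0:
        raise DomainError(f"correlation must lie in [0, 1), got {r}")
    if not 0.0 < case_fraction < 1.0:
        raise DomainError(f"case_fraction must lie in (0, 1), got {case_fraction}")
    pq = case_fraction * (1.0 - case_fraction)
    return r / math.sqrt(pq * (1.0 - r * r))


def d_to_r(d: float, case_fraction: float) -> float:
    """Point-biserial correlation from Cohen's d; inverse of :func:`r_to_d`."""
    if d < 0:
        raise DomainError(f"cohens_d must be >= 0, got {d}")
    if not 0.0 < case_fraction < 1.0:
        raise DomainError(f"case_fraction must lie in (0, 1), got {case_fraction}")
    pq = case_fraction * (1.0 - case_fraction)
    return d * math.sqrt(pq) / math.sqrt(1.0 + d * d * pq)


def or_per_sd_to_d(or_per_sd: float) -> float:
    """Cohen's d from the odds ratio per score standard deviation.

    Uses the logistic-scale conversion d = ln(OR) * sqrt(3)/pi (the logistic
    distribution has SD pi/sqrt(3), so a log-odds slope per SD rescales to a
    standardized mean difference by that constant).
    """
    if or_per_sd < 1.0:
        raise DomainError(
            f"or_per_sd must be >= 1, got {or_per_sd}; if your OR is below 1, "
            "flip the score orientation (higher score => higher risk) first"
        )
    return math.log(or_per_sd) / _LOGISTIC_SD


def d_to_or_per_sd(d: float) -> float:
    """Odds ratio per SD from Cohen's d; inverse of :func:`or_per_sd_to_d`."""
    if d < 0:
        raise DomainError(f"cohens_d must be >= 0, got {d}")
    return math.exp(d * _LOGISTIC_SD)


def _lee_factors(K: float, P: float) -> tuple[float, float]:
    # C and theta of the Lee et al. (2012) observed->liability R² transform
    T = float(norm.ppf(1.0 - K))
    z = float(norm.pdf(T))
    C = K * (1.0 - K) / (z * z) * K * (1.0 - K) / (P * (1.0 - P))
    m = z / K  # mean liability of cases
    u = m * (P - K) / (1.0 - K)
    theta = u * (u - T)
    return C, theta


def r2_observed_to_liability(r2_obs: float, K: float, P: float) -> float:
    """Observed-scale R² to liability-scale R² (Lee et al. 2012).

    The observed scale treats case status as 0/1; the liability scale refers
    to an underlying standard-normal liability with threshold
    T = Phi^{-1}(1-K).  The transform corrects both for the all-or-none
    measurement and for case over-sampling (ascertainment, P != K):

        R²_l = C·R²_o / (1 + C·theta·R²_o)

    with C = K(1-K)/phi(T)² · K(1-K)/(P(1-P)) and theta the ascertainment
    correction, which vanishes when P = K.
    """
    for name, v in (("r2_obs", r2_obs),):
        if not 0.0 <= v < 1.0:
            raise DomainError(f"{name} must lie in [0, 1), got {v}")
    for name, v in (("K", K), ("P", P)):
        if not 0.0 < v < 1.0:
            raise DomainError(f"{name} must lie in (0, 1), got {v}")
    C, theta = _lee_factors(K, P)
    return C * r2_obs / (1.0 + C * theta * r2_obs)


def r2_liability_to_observed(r2_liab: float, K: float, P: float) -> float:
    """Liability-scale R² back to observed scale; inverse of the Lee transform."""
    if not 0.0 <= r2_liab < 1.0:
        raise DomainError(f"r2_liab must lie in [0, 1), got {r2_liab}")
    for name, v in (("K", K), ("P", P)):
        if not 0.0 < v < 1.0:
            raise DomainError(f"{name} must lie in (0, 1), got {v}")
    C, theta = _lee_factors(K, P)
    denom = C * (1.0 - theta * r2_liab)
    if denom <= 0:
        raise DomainError(f"r2_liab={r2_liab} is not attainable at K={K}, P={P}")
    return r2_liab / denom


def any_metric_to_d(m: MetricValue) -> float:
    """Dispatch any accepted binary-outcome metric to Cohen's d.

    ``correlation`` and ``r2_observed`` need the case fraction P of the
    sample they were estimated in; ``r2_liability`` additionally needs the
    prevalence K.  When only the prevalence is supplied, P defaults to K
    (a population-representative sample).
    """
    name, v = m.metric_name, m.value
    if name == "cohens_d":
        if v < 0:
            raise DomainError(f"cohens_d must be >= 0, got {v}")
        return float(v)
    if name == "auc":
        return auc_to_d(v)
    if name == "or_per_sd":
        return or_per_sd_to_d(v)

    P = m.case_fraction if m.case_fraction is not None else m.prevalence
    if name == "correlation":
        if P is None:
            raise MissingContextError(
                "converting a correlation to Cohen's d requires the case "
                "fraction (or prevalence) of the estimation sample"
            )
        return r_to_d(v, P)
    if name == "r2_observed":
        if P is None:
            raise MissingContextError(
                "converting observed-scale R² to Cohen's d requires the case "
                "fraction (or prevalence) of the estimation sample"
            )
        if not 0.0 <= v < 1.0:
            raise DomainError(f"r2_observed must lie in [0, 1), got {v}")
        return r_to_d(math.sqrt(v), P)
    if name == "r2_liability":
        if m.prevalence is None:
            raise MissingContextError(
                "converting liability-scale R² to Cohen's d requires the "
                "population prevalence"
            )
        P = m.case_fraction if m.case_fraction is not None else m.prevalence
        r2_obs = r2_liability_to_observed(v, m.prevalence, P)
        return r_to_d(math.sqrt(r2_obs), P)
    raise DomainError(
        f"metric {name!r} has no conversion to Cohen's d "
        "(r2_continuous applies to continuous phenotypes only)"
    )
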