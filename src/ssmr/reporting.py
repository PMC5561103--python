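"""Report-scale transforms, multiple-testing correction, and power.

Binary-outcome estimates computed on the log-odds scale are reported as odds
ratios per SD of the exposure.  Power for a case-control MR design uses the
standard normal approximation: the asymptotic variance of the IVW log-odds
estimate is 1 / (N R^2 K (1-K)) with N the total sample size, K the case
fraction and R^2 the variance in the exposure explained by the instruments,
giving

    power = Phi( |ln OR| * sqrt(N R^2 K (1-K)) - z_{1-alpha/2} )

and, inverted at a target power,

    detectable OR = exp( (z_power + z_{1-alpha/2}) / sqrt(N R^2 K (1-K)) ).

The negligible opposite-tail term is omitted, so the two functions are exact
inverses of one another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .estimators import MREstimate


@dataclass(frozen=True)
class PowerConfig:
    """Design of a binary-outcome MR power calculation."""

    n_total: int
    n_cases: int
    r2: float
    alpha: float = 0.05
    target_power: float = 0.8

    def __post_init__(self) -> None:
        if not (0 < self.n_cases < self.n_total):
            raise ValueError("need 0 < n_cases < n_total")
        if not (0 < self.r2 < 1):
            raise ValueError("r2 must be in (0,1)")
        if not (0 < self.alpha < 1) or not (0 < self.target_power < 1):
            raise ValueError("alpha and target_power must be in (0,1)")

    @property
    def case_fraction(self) -> float:
        return self.n_cases / self.n_total

    @property
    def _scale(self) -> float:
        k = self.case_fraction
        return math.sqrt(self.n_total * self.r2 * k * (1 - k))


@dataclass(frozen=True)
class OddsRatioEstimate:
    method: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    ci_kind: str = "interval"


def to_odds_ratio(est: MREstimate) -> OddsRatioEstimate:
    """Exponentiate a log-odds estimate and its CI endpoints.

    Non-finite confidence sets (exclusive Fieller regions, the whole line)
    keep their flag; endpoints at +/-inf map to 0/inf.
    """
    return OddsRatioEstimate(
        method=est.method,
        odds_ratio=math.exp(est.estimate),
        ci_low=math.exp(est.ci_low) if math.isfinite(est.ci_low) else 0.0,
        ci_high=math.exp(est.ci_high) if math.isfinite(est.ci_high) else math.inf,
        pvalue=est.pvalue,
        n_snps=est.n_snps,
        ci_kind=est.ci_kind,
    )


def bonferroni_threshold(alpha: float, n_traits: int, n_exposures: int = 1) -> float:
    """Study-wide significance threshold alpha / (n_traits * n_exposures)."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0,1)")
    if n_traits < 1 or n_exposures < 1:
        raise ValueError("comparison counts must be positive integers")
    return alpha / (n_traits * n_exposures)


def power_binary(cfg: PowerConfig, odds_ratio: float) -> float:
    """Power to detect ``odds_ratio`` per SD exposure at two-sided cfg.alpha."""
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be positive")
    z_alpha = stats.norm.ppf(1 - cfg.alpha / 2)
    return float(stats.norm.cdf(abs(math.log(odds_ratio)) * cfg._scale - z_alpha))


def detectable_or(cfg: PowerConfig) -> float:
    """Minimal detectable odds ratio (>1) at cfg.target_power."""
    z_alpha = stats.norm.ppf(1 - cfg.alpha / 2)
    z_power = stats.norm.ppf(cfg.target_power)
    return float(math.exp((z_power + z_alpha) / cfg._scale))


def format_or(value: float, decimals: int = 2) -> str:
    """Round for report tables (2 decimals; 3 kept when the 2-decimal form
    would hide the direction, e.g. 1.005)."""
    two = round(value, decimals)
    if value != 1.0 and two == 1.0:
        return f"{value:.3f}"
    return f"{two:.{decimals}f}"
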