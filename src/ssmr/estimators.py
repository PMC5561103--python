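"""Causal-effect estimators and diagnostics for two-sample summary-data MR.

Given per-variant exposure effects beta_X (with se_X) and outcome effects
beta_Y (with se_Y) aligned on a common effect allele, the causal effect of a
1-SD change in the exposure on the outcome (log odds for binary outcomes) is
estimated by:

* the per-variant Wald ratio beta_Y / beta_X, with a first-order delta-method
  standard error and, optionally, a Fieller confidence set (exact for a ratio
  of normal means; may be a finite interval, the complement of an interval,
  or the whole line);
* fixed-effect inverse-variance weighting (IVW) of the Wald ratios, with
  weights beta_X^2 / se_Y^2 — algebraically the slope of a through-origin
  weighted regression of beta_Y on beta_X;
* generalised weighted least squares for correlated variants, with outcome
  covariance Omega_jk = se_Y_j se_Y_k rho_jk;
* the weighted median of the Wald ratios (consistent while valid instruments
  carry more than half the weight), with a parametric-bootstrap SE;
* MR-Egger regression (weighted, with a free intercept) whose slope is the
  causal estimate under the InSIDE assumption and whose intercept estimates
  the average directional pleiotropic effect.

Cochran's Q against the IVW estimate quantifies heterogeneity between the
per-variant ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from .io import HarmonizedTable

Method = Literal[
    "wald", "ivw_fixed", "ivw_correlated", "weighted_median", "egger_slope", "egger_intercept"
]


@dataclass(frozen=True)
class MREstimate:
    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    ci_kind: str = "interval"  # 'interval' | 'exclusive' | 'real_line'

    def __post_init__(self) -> None:
        if self.ci_kind == "interval" and not (
            self.ci_low - 1e-12 <= self.estimate <= self.ci_high + 1e-12
        ):
            raise ValueError(
                f"{self.method}: estimate {self.estimate} outside CI "
                f"[{self.ci_low}, {self.ci_high}]"
            )


@dataclass(frozen=True)
class FiellerSet:
    """Fieller confidence set for a ratio of normal means.

    kind 'interval': {theta in [low, high]}; 'exclusive': the complement
    {theta <= low or theta >= high}; 'real_line': every theta is compatible.
    """

    kind: str
    low: float
    high: float

    def contains(self, theta: float) -> bool:
        if self.kind == "real_line":
            return True
        inside = self.low <= theta <= self.high
        return inside if self.kind == "interval" else not inside


@dataclass(frozen=True)
class HeterogeneityResult:
    Q: float
    df: int
    pvalue: float


def _normal_ci_p(estimate: float, se: float, alpha: float) -> tuple[float, float, float]:
    z = stats.norm.ppf(1 - alpha / 2)
    p = 2 * stats.norm.sf(abs(estimate) / se) if se > 0 else (1.0 if estimate == 0 else 0.0)
    return estimate - z * se, estimate + z * se, max(p, 5e-324)


def wald_ratio(
    beta_x: float, se_x: float, beta_y: float, se_y: float, alpha: float = 0.05
) -> MREstimate:
    """Single-variant causal estimate beta_Y/beta_X with delta-method SE."""
    if beta_x == 0:
        raise ZeroDivisionError("Wald ratio undefined: beta_x = 0")
    if se_y <= 0 or se_x < 0:
        raise ValueError("standard errors must be positive (se_x may be 0 for exact exposure)")
    est = beta_y / beta_x
    se = abs(1 / beta_x) * math.sqrt(se_y**2 + est**2 * se_x**2)
    lo, hi, p = _normal_ci_p(est, se, alpha)
    return MREstimate("wald", est, se, lo, hi, p, 1)


def fieller_interval(
    beta_x: float, se_x: float, beta_y: float, se_y: float, alpha: float = 0.05
) -> FiellerSet:
    """Fieller confidence set {theta : (bY - theta bX)^2 <= z^2 (seY^2 + theta^2 seX^2)}.

    With A = bX^2 - z^2 seX^2, B = bX bY, C = bY^2 - z^2 seY^2 the boundary is
    the quadratic A theta^2 - 2B theta + C = 0.  A > 0 (the exposure effect is
    itself significant at level alpha) guarantees a positive discriminant and
    a finite interval; A < 0 yields the complement of an interval when the
    discriminant is nonnegative and the whole line otherwise.
    """
    if se_x <= 0 or se_y <= 0:
        raise ValueError("standard errors must be positive")
    z = stats.norm.ppf(1 - alpha / 2)
    a = beta_x**2 - z**2 * se_x**2
    b = beta_x * beta_y
    c = beta_y**2 - z**2 * se_y**2
    disc = b**2 - a * c
    if a > 0:
        root = math.sqrt(max(disc, 0.0))
        return FiellerSet("interval", (b - root) / a, (b + root) / a)
    if disc >= 0 and a < 0:
        root = math.sqrt(disc)
        # complement: quadratic is <= 0 outside the roots when a < 0
        lo, hi = sorted(((b - root) / a, (b + root) / a))
        return FiellerSet("exclusive", lo, hi)
    return FiellerSet("real_line", -math.inf, math.inf)


def _ivw_weights(h: HarmonizedTable) -> np.ndarray:
    if np.any(h.beta_x == 0):
        bad = [s for s, b in zip(h.snps, h.beta_x) if b == 0]
        raise ZeroDivisionError(f"beta_x = 0 for {bad}; filter before IVW")
    return h.beta_x**2 / h.se_y**2


def ivw_fixed(h: HarmonizedTable, alpha: float = 0.05) -> MREstimate:
    """Fixed-effect IVW estimate: precision-weighted mean of the Wald ratios."""
    if len(h) < 1:
        raise ValueError("IVW needs at least one variant")
    w = _ivw_weights(h)
    ratios = h.beta_y / h.beta_x
    est = float(np.sum(w * ratios) / np.sum(w))
    se = float(1 / math.sqrt(np.sum(w)))
    lo, hi, p = _normal_ci_p(est, se, alpha)
    return MREstimate("ivw_fixed", est, se, lo, hi, p, len(h))


def ivw_correlated(
    h: HarmonizedTable, rho: np.ndarray, alpha: float = 0.05
) -> MREstimate:
    """Generalised weighted regression through the origin for correlated variants."""
    rho = np.asarray(rho, float)
    m = len(h)
    if rho.shape != (m, m):
        raise ValueError(f"LD matrix shape {rho.shape} does not match {m} variants")
    if not np.allclose(rho, rho.T):
        raise ValueError("LD matrix must be symmetric")
    eigvals = np.linalg.eigvalsh(rho)
    if eigvals[0] <= 0:
        raise np.linalg.LinAlgError(
            f"LD matrix not positive definite (min eigenvalue {eigvals[0]:.3g})"
        )
    omega = np.outer(h.se_y, h.se_y) * rho
    oinv_bx = np.linalg.solve(omega, h.beta_x)
    denom = float(h.beta_x @ oinv_bx)
    est = float(oinv_bx @ h.beta_y) / denom
    se = 1 / math.sqrt(denom)
    lo, hi, p = _normal_ci_p(est, se, alpha)
    return MREstimate("ivw_correlated", est, se, lo, hi, p, m)


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated 50% point of the weighted empirical distribution."""
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / np.sum(weights)
    cum = np.cumsum(w) - w / 2
    if 0.5 <= cum[0]:
        return float(r[0])
    if 0.5 >= cum[-1]:
        return float(r[-1])
    return float(np.interp(0.5, cum, r))


def weighted_median(
    h: HarmonizedTable, n_boot: int = 1000, seed: int | None = None, alpha: float = 0.05
) -> MREstimate:
    """Weighted-median causal estimate with a parametric-bootstrap SE.

    Weights are inverse delta-method Wald-ratio variances.  The SE is the
    standard deviation of the estimate over ``n_boot`` resamples of
    (beta_X, beta_Y) from independent normals at their stated SEs.
    """
    if len(h) < 3:
        raise ValueError(f"weighted median needs >= 3 variants, got {len(h)}")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    bx, sx, by, sy = h.beta_x, h.se_x, h.beta_y, h.se_y
    ratios = by / bx
    var = (sy**2 + ratios**2 * sx**2) / bx**2
    est = _weighted_median(ratios, 1 / var)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for i in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        rs = bys / bxs
        vs = (sy**2 + rs**2 * sx**2) / bxs**2
        boot[i] = _weighted_median(rs, 1 / vs)
    se = float(np.std(boot, ddof=1))
    lo, hi, p = _normal_ci_p(est, se, alpha)
    return MREstimate("weighted_median", est, se, lo, hi, p, len(h))


def mr_egger(
    h: HarmonizedTable,
    alpha: float = 0.05,
    residual_scale: bool = False,
    t_dist: bool = False,
) -> tuple[MREstimate, MREstimate]:
    """MR-Egger weighted regression; returns (slope, intercept) estimates.

    Every variant is first oriented so its exposure effect is positive
    (flipping the outcome beta accordingly) — the intercept is only
    interpretable as the average directional pleiotropic effect in that
    orientation.  Weights are 1/se_Y^2, treated as known precisions
    (fixed-effect convention, matching the IVW weighting); an intercept
    p-value below 0.05 is the conventional signal of directional pleiotropy.
    ``residual_scale`` switches to the multiplicative random-effect variant
    (SEs scaled by the residual dispersion, never below 1), and ``t_dist``
    to a t reference with m-2 df; inference is normal by default.
    """
    m = len(h)
    if m < 3:
        raise ValueError(f"MR-Egger needs >= 3 variants, got {m}")
    sign = np.sign(h.beta_x)
    if np.any(sign == 0):
        raise ZeroDivisionError("beta_x = 0; filter before MR-Egger")
    bx = h.beta_x * sign
    by = h.beta_y * sign
    w = 1 / h.se_y**2
    sw = np.sum(w)
    swx = np.sum(w * bx)
    sxx = np.sum(w * bx**2) - swx**2 / sw
    if sxx <= 1e-10 * float(np.sum(w * bx**2)):
        raise np.linalg.LinAlgError("singular design: no spread in |beta_x|")
    sxy = np.sum(w * bx * by) - swx * np.sum(w * by) / sw
    slope = float(sxy / sxx)
    intercept = float((np.sum(w * by) - slope * swx) / sw)
    if residual_scale:
        resid = by - intercept - slope * bx
        sigma2 = max(float(np.sum(w * resid**2) / (m - 2)), 1.0)
    else:
        sigma2 = 1.0
    se_slope = math.sqrt(sigma2 / sxx)
    se_inter = math.sqrt(sigma2 * (1 / sw + swx**2 / (sw**2 * sxx)))
    if t_dist:
        q = stats.t.ppf(1 - alpha / 2, m - 2)
        p_s = 2 * stats.t.sf(abs(slope) / se_slope, m - 2)
        p_i = 2 * stats.t.sf(abs(intercept) / se_inter, m - 2)
        slope_ci = (slope - q * se_slope, slope + q * se_slope)
        inter_ci = (intercept - q * se_inter, intercept + q * se_inter)
        slope_est = MREstimate("egger_slope", slope, se_slope, *slope_ci, max(p_s, 5e-324), m)
        inter_est = MREstimate(
            "egger_intercept", intercept, se_inter, *inter_ci, max(p_i, 5e-324), m
        )
    else:
        lo, hi, p_s = _normal_ci_p(slope, se_slope, alpha)
        slope_est = MREstimate("egger_slope", slope, se_slope, lo, hi, p_s, m)
        lo, hi, p_i = _normal_ci_p(intercept, se_inter, alpha)
        inter_est = MREstimate("egger_intercept", intercept, se_inter, lo, hi, p_i, m)
    return slope_est, inter_est


def cochran_q(h: HarmonizedTable, theta_ivw: float | None = None) -> HeterogeneityResult:
    """Cochran's Q heterogeneity test of the Wald ratios against the IVW estimate."""
    if len(h) < 2:
        raise ValueError("Cochran's Q needs >= 2 variants")
    w = _ivw_weights(h)
    ratios = h.beta_y / h.beta_x
    if theta_ivw is None:
        theta_ivw = float(np.sum(w * ratios) / np.sum(w))
    q = float(np.sum(w * (ratios - theta_ivw) ** 2))
    df = len(h) - 1
    return HeterogeneityResult(q, df, float(stats.chi2.sf(q, df)))
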