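"""Synthetic two-sample GWAS summary statistics.

The generator emits exposure-side and outcome-side association tables with
the statistical structure the estimators assume.  Per variant j a true
exposure effect gamma_j is drawn (magnitude uniform on
[0.5, 1.5] * gamma_scale with random sign — instruments are genome-wide
significant hits, bounded away from zero, not draws from a null-centred
distribution); the observed effects are

    beta_X_j = gamma_j + eps_X_j,          eps_X_j ~ N(0, se_X_j^2)
    beta_Y_j = theta * gamma_j + alpha_j + eps_Y_j,  eps_Y_j ~ N(0, se_Y_j^2)

where theta is the true causal effect (log odds per SD for a binary outcome;
effects are simulated directly on the summary scale, no individual-level
sampling) and alpha_j is a direct (pleiotropic) effect on the outcome:

* ``none``        alpha_j = 0 (all instruments valid);
* ``balanced``    alpha_j ~ N(0, alpha_sd^2) on the invalid fraction;
* ``directional`` alpha_j ~ N(alpha_mean, alpha_sd^2), independent of
  instrument strength |gamma_j|, so the InSIDE condition holds and the
  MR-Egger slope remains consistent while IVW is biased;
* ``inside_violating`` alpha_j proportional to |gamma_j| (plus noise), so
  pleiotropy is correlated with instrument strength and even MR-Egger is
  biased.

alpha_j is defined relative to the exposure-increasing allele — the
orientation in which directional pleiotropy is directional — so the term
entering beta_Y is sign(gamma_j) * alpha_j; ``TruthRecord.alpha`` stores the
increasing-allele value.

Per-SNP standard errors vary uniformly within +/-20% of their scale.  If an
LD correlation matrix is supplied the sampling-noise vectors are drawn
jointly with that correlation on both sides.  Emitted p-values are the
two-sided normal p implied by beta/se, so significance filtering behaves
consistently; allele pairs are non-palindromic, and the outcome table's
allele orientation is randomly swapped per SNP so harmonization is
exercised end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .io import VariantAssociation

# magnitude ~ U(0.5,1.5)*scale and se multiplier ~ U(0.8,1.2) give
# E[gamma^2] = 13/12 * scale^2 and E[1/se^2] = 25/24 / se_scale^2
_E_GAMMA2 = 13.0 / 12.0
_E_INV_SE2 = 25.0 / 24.0

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "A")]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic two-sample dataset."""

    m: int = 20
    theta: float = 0.0
    gamma_scale: float = 0.1
    se_x_scale: float = 0.0136
    se_y_scale: float = 0.02
    pleiotropy_mode: str = "none"  # none | balanced | directional | inside_violating
    alpha_mean: float = 0.0
    alpha_sd: float = 0.0
    invalid_fraction: float = 1.0
    rho: np.ndarray | None = None
    n_exposure: int = 26_420
    n_outcome: int = 195_055
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.gamma_scale <= 0 or self.se_x_scale <= 0 or self.se_y_scale <= 0:
            raise ValueError("scales must be positive")
        if not (0 <= self.invalid_fraction <= 1):
            raise ValueError("invalid_fraction must be in [0,1]")
        if self.pleiotropy_mode not in {"none", "balanced", "directional", "inside_violating"}:
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")


@dataclass
class TruthRecord:
    """Ground truth behind one simulated dataset."""

    theta: float
    gamma: dict[str, float] = field(default_factory=dict)
    alpha: dict[str, float] = field(default_factory=dict)
    invalid: list[str] = field(default_factory=list)


def se_x_scale_for_mean_f(gamma_scale: float, target_mean_f: float) -> float:
    """Exposure-side SE scale giving a target mean per-variant F-statistic.

    With the generator's distributions, E[F] = E[(gamma+eps)^2/se^2]
    = 1 + E[gamma^2] E[1/se^2] = 1 + (13/12)(25/24)(gamma_scale/se_scale)^2,
    solved for se_scale.
    """
    if target_mean_f <= 1:
        raise ValueError("target mean F must exceed 1")
    return gamma_scale * math.sqrt(_E_GAMMA2 * _E_INV_SE2 / (target_mean_f - 1))


def simulate_ld_matrix(
    m: int, block_size: int, within_block_r: float, seed: int | None = None
) -> np.ndarray:
    """Block-diagonal exchangeable correlation matrix (deterministic given its
    shape parameters; ``seed`` is accepted for interface symmetry)."""
    if not abs(within_block_r) < 1:
        raise ValueError("|within_block_r| must be < 1")
    if block_size < 1 or m < 1:
        raise ValueError("m and block_size must be >= 1")
    if block_size > 1 and within_block_r <= -1.0 / (block_size - 1):
        raise ValueError(
            f"r = {within_block_r} makes a {block_size}-wide exchangeable block "
            "non positive definite"
        )
    rho = np.eye(m)
    for start in range(0, m, block_size):
        stop = min(start + block_size, m)
        block = np.full((stop - start, stop - start), within_block_r)
        np.fill_diagonal(block, 1.0)
        rho[start:stop, start:stop] = block
    return rho


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    z = np.abs(beta / se)
    return np.clip(np.vectorize(math.erfc)(z / math.sqrt(2.0)), 5e-324, 1.0)


def simulate_two_sample(
    cfg: SimulationConfig,
) -> tuple[list[VariantAssociation], list[VariantAssociation], TruthRecord]:
    """Draw one synthetic dataset; returns (exposure table, outcome table, truth)."""
    rng = np.random.default_rng(cfg.seed)
    m = cfg.m
    snps = [f"rs{1000 + i}" for i in range(m)]

    gamma = rng.uniform(0.5, 1.5, m) * cfg.gamma_scale * rng.choice([-1.0, 1.0], m)
    se_x = cfg.se_x_scale * rng.uniform(0.8, 1.2, m)
    se_y = cfg.se_y_scale * rng.uniform(0.8, 1.2, m)

    n_invalid = int(round(cfg.invalid_fraction * m)) if cfg.pleiotropy_mode != "none" else 0
    invalid_idx = rng.choice(m, size=n_invalid, replace=False) if n_invalid else np.array([], int)
    alpha = np.zeros(m)
    if cfg.pleiotropy_mode == "balanced":
        alpha[invalid_idx] = rng.normal(0.0, cfg.alpha_sd, n_invalid)
    elif cfg.pleiotropy_mode == "directional":
        alpha[invalid_idx] = rng.normal(cfg.alpha_mean, cfg.alpha_sd, n_invalid)
    elif cfg.pleiotropy_mode == "inside_violating":
        alpha[invalid_idx] = (
            cfg.alpha_mean * np.abs(gamma[invalid_idx]) / cfg.gamma_scale
            + rng.normal(0.0, cfg.alpha_sd, n_invalid)
        )

    if cfg.rho is not None:
        rho = np.asarray(cfg.rho, float)
        if rho.shape != (m, m) or not np.allclose(rho, rho.T):
            raise ValueError("rho must be a symmetric m x m matrix")
        if np.linalg.eigvalsh(rho)[0] <= 0:
            raise ValueError("rho must be positive definite")
        chol = np.linalg.cholesky(rho)
        eps_x = se_x * (chol @ rng.standard_normal(m))
        eps_y = se_y * (chol @ rng.standard_normal(m))
    else:
        eps_x = rng.normal(0.0, se_x)
        eps_y = rng.normal(0.0, se_y)

    beta_x = gamma + eps_x
    beta_y = cfg.theta * gamma + np.sign(gamma) * alpha + eps_y
    p_x = _two_sided_p(beta_x, se_x)
    p_y = _two_sided_p(beta_y, se_y)
    eaf = rng.uniform(0.1, 0.9, m)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), m)
    swap = rng.random(m) < 0.5  # outcome table reports the opposite allele

    exposure, outcome = [], []
    for j, snp in enumerate(snps):
        ea, oa = _ALLELE_PAIRS[pair_idx[j]]
        exposure.append(
            VariantAssociation(snp, ea, oa, float(beta_x[j]), float(se_x[j]),
                               float(p_x[j]), float(eaf[j]), cfg.n_exposure)
        )
        if swap[j]:
            outcome.append(
                VariantAssociation(snp, oa, ea, -float(beta_y[j]), float(se_y[j]),
                                   float(p_y[j]), float(1 - eaf[j]), cfg.n_outcome)
            )
        else:
            outcome.append(
                VariantAssociation(snp, ea, oa, float(beta_y[j]), float(se_y[j]),
                                   float(p_y[j]), float(eaf[j]), cfg.n_outcome)
            )
    truth = TruthRecord(
        theta=cfg.theta,
        gamma=dict(zip(snps, gamma.tolist())),
        alpha=dict(zip(snps, alpha.tolist())),
        invalid=[snps[i] for i in sorted(invalid_idx.tolist())],
    )
    return exposure, outcome, truth


# Scenario presets mirroring the analysed instrument sets: SNP counts 20/22
# (TSH against the two CAD/MI studies), 5 (FT4), 2 (TPOAb positivity), with
# exposure-side noise set so the mean F-statistic matches each design.
PRESETS: dict[str, SimulationConfig] = {
    "tsh_like_20snp": SimulationConfig(
        m=20, se_x_scale=se_x_scale_for_mean_f(0.1, 59.3)),
    "tsh_like_22snp": SimulationConfig(
        m=22, se_x_scale=se_x_scale_for_mean_f(0.1, 58.3)),
    "ft4_like_5snp": SimulationConfig(
        m=5, se_x_scale=se_x_scale_for_mean_f(0.1, 61.4)),
    "tpoab_like_2snp": SimulationConfig(
        m=2, se_x_scale=se_x_scale_for_mean_f(0.1, 33.4)),
}


def preset(name: str, seed: int | None = None, **overrides) -> SimulationConfig:
    """Look up a named scenario, optionally re-seeding or overriding fields."""
    try:
        cfg = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}") from None
    if seed is not None:
        overrides["seed"] = seed
    return replace(cfg, **overrides) if overrides else cfg
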