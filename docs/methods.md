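# Methods

## Model

Two-sample (separate-sample) Mendelian randomization treats genetic
variants as instrumental variables for an exposure X when estimating its
causal effect θ on an outcome Y. For variant j, let β_Xj (SE σ_Xj) be its
association with the exposure from one study sample and β_Yj (SE σ_Yj) its
association with the outcome from a non-overlapping sample, both expressed
per copy of a common effect allele. If variant j affects Y only through X
(no horizontal pleiotropy), is associated with X, and shares no confounder
with Y, then β_Yj = θ·β_Xj and every Wald ratio θ̂_j = β_Yj/β_Xj estimates
θ. For binary outcomes the β_Y are log odds ratios and θ is a log odds
ratio per SD of the exposure; estimation proceeds identically on that scale
(non-collapsibility makes the result an approximation to the conditional
effect, as is standard for summary-data MR with case-control outcomes).

## Estimators

* **Wald ratio.** θ̂_j = β_Yj/β_Xj; first-order delta-method SE
  |1/β_Xj|·√(σ_Yj² + θ̂_j²σ_Xj²). Accurate when the instrument is strong
  (F_j = (β_Xj/σ_Xj)² large); the simulation check in the test suite uses
  F = 100 because the ratio's tails visibly exceed the first-order
  expansion already at F ≈ 25.
* **Fieller confidence set.** The exact set
  {θ : (β_Y − θβ_X)² ≤ z²(σ_Y² + θ²σ_X²)}. With A = β_X² − z²σ_X²,
  B = β_Xβ_Y, C = β_Y² − z²σ_Y², the boundary roots are
  (B ± √(B² − AC))/A. A > 0 (exposure association itself significant at
  level α) forces B² − AC > 0 and a finite interval; A < 0 with nonnegative
  discriminant gives the complement of an interval; a negative discriminant
  (only possible when A < 0) gives the whole real line. A = 0 is a
  measure-zero boundary case returned as an unbounded set. The Fieller set
  is reported alongside, never collapsed into, the delta-method SE.
* **Fixed-effect IVW.** θ̂ = Σw_jθ̂_j/Σw_j with w_j = β_Xj²/σ_Yj²,
  SE = (Σw_j)^{−1/2}; algebraically the through-origin weighted
  least-squares slope of β_Y on β_X with weights 1/σ_Yj². First-order
  weights (exposure-side noise ignored) are the fixed-effect IVW
  convention; a second-order option was considered and rejected to keep
  the estimator the standard one the diagnostics (Q) assume.
* **Correlated variants.** When instruments are in LD with correlation
  matrix ρ, θ̂ = (β_XᵀΩ⁻¹β_X)⁻¹β_XᵀΩ⁻¹β_Y with Ω_jk = σ_Yjσ_Ykρ_jk,
  SE = (β_XᵀΩ⁻¹β_X)^{−1/2}. ρ must be symmetric positive definite; the
  offending eigenvalue is named otherwise. With ρ = I this reduces exactly
  to fixed-effect IVW (tested to machine tolerance).
* **Weighted median.** Wald ratios sorted ascending; with normalized
  inverse-variance weights (delta-method variances) the estimate linearly
  interpolates the weighted CDF midpoints p_j = (S_j − w_j/2)/S_m at 0.5.
  Consistent while valid instruments carry more than half the weight. The
  SE is a parametric bootstrap: n_boot (default 1000, seeded) resamples of
  (β_X, β_Y) from independent normals at their stated SEs.
* **MR-Egger.** Variants are oriented so every β_Xj > 0, then β_Y is
  regressed on β_X with a free intercept and weights 1/σ_Yj². The slope
  estimates θ under InSIDE (instrument strength independent of direct
  effects); the intercept estimates the average directional pleiotropic
  effect, with p < 0.05 the conventional signal of directional pleiotropy.
* **Cochran's Q.** Q = Σw_j(θ̂_j − θ̂_IVW)² with the IVW weights, referred
  to χ²(m−1).

## Inference conventions

IVW, GLS and Egger p-values and CIs use the normal reference with weights
treated as known precisions (fixed-effect convention). This makes the
Egger intercept test exactly calibrated under the null of no pleiotropy
with correctly stated SEs — the property the calibration tests assert. A
multiplicative random-effect variant (SEs scaled by residual dispersion,
never deflated) and a t reference with m−2 df are available via
`mr_egger(..., residual_scale=True, t_dist=True)` for heterogeneous data.
No SIMEX or I²_GX weak-instrument correction for Egger is provided.

## Instrument selection

Filters run in the order: significance (retained iff p < 5×10⁻⁸, strict),
LD pruning, availability in the outcome study, pleiotropy exclusion. LD
pruning visits pairs with r² above the threshold (default 0.7) in
descending r² (ties broken lexicographically on the rsID pair) and discards
the member with the larger exposure p-value (ties: lexicographically larger
rsID); exclusions cascade, so an excluded variant eliminates no further
variants. The deterministic order makes runs reproducible and matches a
greedy remove-the-worst-offender oracle. Pleiotropy screening is delegated
to user-supplied exclusion lists (annotation databases are consulted
offline); both the excluding ("without pleiotropy") and the including
("all SNPs") instrument sets are always analysed and reported. Per-variant
instrument strength is F_j = (β_Xj/σ_Xj)², the standard two-sample
approximation; an R²/n-based alternative is available as
`f_statistic_from_r2`.

## Harmonization

Variants are matched by rsID only (consortium tables are rsID-keyed; no
chr:pos fallback). The outcome β is sign-flipped (and its EAF
complemented) when the outcome's effect allele equals the exposure's other
allele directly or after strand complementing. Palindromic variants carry
no strand information: the default policy drops them; `infer-by-eaf`
orients them by allele frequency when both EAFs lie outside
0.5 ± `eaf_window` (default 0.08) and drops them otherwise. Missing EAF
only matters for that policy. Incompatible allele sets are dropped with
reason "allele mismatch". Harmonization is idempotent and invariant to
flipping both alleles and the β sign of any outcome row.

## Power

For a case-control outcome with N participants, case fraction K, and
instruments explaining R² of the exposure variance, the IVW log-odds
estimate has asymptotic variance 1/(N·R²·K(1−K)), giving
power = Φ(|ln OR|·√(N·R²·K(1−K)) − z_{1−α/2}) and minimal detectable
OR = exp((z_power + z_{1−α/2})/√(N·R²·K(1−K))). The negligible
opposite-tail term is omitted so the two functions are exact inverses
(round-trip tested to 10⁻¹⁰). Bonferroni correction divides α by the
number of outcome traits times exposures. Report tables round ORs and CIs
to two decimals, keeping a third decimal when rounding would hide the
direction of effect (e.g. 1.005).

## Synthetic data generator

The generator emulates the summary statistics the estimators consume:
true per-variant exposure effects γ_j with |γ_j| ~ U(0.5, 1.5)·`gamma_scale`
and random sign (instruments are genome-wide hits, bounded away from zero,
not null-centred draws), observed β_Xj = γ_j + ε_Xj and
β_Yj = θγ_j + sign(γ_j)·α_j + ε_Yj, with per-variant SEs varying uniformly
within ±20 % of their scales and ε drawn jointly with a supplied LD
correlation when given. Pleiotropic effects α_j are defined relative to the
exposure-increasing allele (the orientation in which "directional" is
meaningful): zero (`none`), centred normal (`balanced`), mean-shifted
normal independent of strength (`directional`, InSIDE holds), or
proportional to |γ_j| (`inside_violating`). Emitted p-values are exactly
the two-sided normal p implied by β/σ, allele pairs are non-palindromic,
and the outcome table's allele orientation is randomly swapped per variant
so harmonization is exercised end to end; a fixed seed fixes every emitted
byte.

Defaults are chosen as a realistic consortium-scale design: `gamma_scale`
0.1 per-SD, outcome σ_Y 0.02 on the log-odds scale, exposure study
n = 26,420 and outcome study n = 195,055. `se_x_scale_for_mean_f` derives
the exposure-side noise scale for a target mean F analytically
(E[F] = 1 + (13/12)(25/24)(γ_scale/σ_X)²), so "mean F ≈ 60" scenarios are
parameterised a priori. Scenario presets mirror the analysed instrument
sets: 20 and 22 variants (TSH against the two CAD/MI studies, mean F 59.3
and 58.3), 5 (FT4, mean F 61.4) and 2 (TPOAb positivity, mean F 33.4).

What the generator does **not** emulate: realistic allele-frequency
spectra, individual-level genotype sampling, selection effects of GWAS
discovery (winner's curse), overlapping samples, or population
stratification. Passing tests therefore demonstrate correctness of the
estimators under their stated assumptions, not robustness to those
real-data complications.

## Simulation sizes and numerical choices

Calibration experiments use 2000 replicates (null rejection rates,
intercept-p uniformity) and 1000 replicates (CI coverage, pleiotropy bias
decomposition) of 20-variant designs at mean F ≈ 60 — large enough that
binomial Monte-Carlo error (±1.5 percentage points at 3σ for a 5 % rate)
separates calibrated from miscalibrated behaviour, and small enough to run
in seconds. Oracle-equivalence checks run 100 random instances per
estimator at 10⁻¹⁰ relative tolerance. The Egger singular-design guard
triggers when the weighted spread of |β_X| falls below 10⁻¹⁰ of its raw
second moment. The weighted-median bootstrap defaults to 1000 resamples.
Degenerate inputs (β_X = 0 ratios, non-PD LD matrices, < 3 variants for
median/Egger, empty instrument sets after filtering) raise typed errors or
are skipped with a logged reason at the pipeline level, where one failed
analysis never aborts the remaining ones.

## Known limitations

* Binary-outcome effects are combined on the log-odds scale; for
  case-control outcomes the estimate approximates the conditional odds
  ratio (non-collapsibility).
* No random-effects IVW, mode-based estimators, or multivariable MR.
* Proxy lookup and pleiotropy annotation are user inputs, not automated
  queries.
* The power formula is the normal approximation for IVW with a binary
  outcome; continuous-outcome power is out of scope.
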