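"""Causal estimators and diagnostics against independent oracles.

Each estimator is checked against a route that shares no code with it:
statsmodels WLS fits for IVW and MR-Egger, extended-precision matrix algebra
for the correlated-variant GLS, a grid/root-finding scan of the defining
inequality for Fieller sets, an explicit CDF scan for the weighted median,
and Monte-Carlo simulation for the Wald-ratio delta-method SE.
"""

import math

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import optimize, stats

from conftest import make_harmonized
from ssmr import (
    HarmonizedTable,
    cochran_q,
    fieller_interval,
    ivw_correlated,
    ivw_fixed,
    mr_egger,
    wald_ratio,
    weighted_median,
)


class TestWaldRatio:
    def test_exact_when_exposure_noiseless(self):
        est = wald_ratio(1.0, 0.0, 0.5, 0.1)
        assert est.estimate == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_zero_outcome_effect(self):
        est = wald_ratio(0.1, 0.02, 0.0, 0.01)
        assert est.estimate == 0.0
        assert est.se == pytest.approx(0.01 / 0.1)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.02, 0.03, 0.01)

    def test_delta_method_se_matches_simulation(self, rng):
        bx, sx, by, sy = 0.1, 0.01, 0.03, 0.01  # F = 100: delta method valid
        est = wald_ratio(bx, sx, by, sy)
        draws = rng.normal(by, sy, 10**6) / rng.normal(bx, sx, 10**6)
        # trim the far tails the first-order expansion cannot represent
        lo, hi = np.quantile(draws, [0.001, 0.999])
        sd = np.std(draws[(draws > lo) & (draws < hi)])
        assert est.se == pytest.approx(sd, rel=0.05)


class TestFieller:
    def test_converges_to_delta_interval_as_se_x_vanishes(self):
        bx, by, sy = 0.1, 0.03, 0.01
        z = stats.norm.ppf(0.975)
        fs = fieller_interval(bx, 1e-9, by, sy)
        assert fs.kind == "interval"
        assert fs.low == pytest.approx(by / bx - z * sy / bx, rel=1e-4)
        assert fs.high == pytest.approx(by / bx + z * sy / bx, rel=1e-4)

    def test_weak_exposure_gives_non_finite_set(self):
        # A = 0.05^2 - 1.96^2 * 0.05^2 < 0: exposure not significant at alpha
        fs = fieller_interval(0.05, 0.05, 0.03, 0.01)
        assert fs.kind in {"exclusive", "real_line"}

    def test_whole_line_when_nothing_significant(self):
        fs = fieller_interval(0.01, 0.05, 0.001, 0.05)
        assert fs.kind == "real_line"
        assert fs.contains(-1e6) and fs.contains(1e6)

    @staticmethod
    def _oracle(bx, sx, by, sy, alpha=0.05, span=10.0):
        """Grid scan + Brent refinement of g(t) = (bY-t bX)^2 - z^2(seY^2+t^2 seX^2)."""
        z = stats.norm.ppf(1 - alpha / 2)

        def g(t):
            return (by - t * bx) ** 2 - z**2 * (sy**2 + t**2 * sx**2)

        grid = np.linspace(-span, span, 40001)
        vals = g(grid)
        roots = []
        for i in np.flatnonzero(np.diff(np.sign(vals)) != 0):
            roots.append(optimize.brentq(g, grid[i], grid[i + 1], xtol=1e-12))
        inside = vals <= 0
        return roots, inside

    def test_endpoints_match_root_finding_oracle(self, rng):
        for _ in range(100):
            bx = rng.normal(0.1, 0.05)
            sx = rng.uniform(0.005, 0.05)
            by = rng.normal(0.02, 0.03)
            sy = rng.uniform(0.005, 0.05)
            fs = fieller_interval(bx, sx, by, sy)
            roots, inside = self._oracle(bx, sx, by, sy)
            if fs.kind == "real_line":
                assert not roots and inside.all()
                continue
            finite = [r for r in (fs.low, fs.high) if abs(r) < 10]
            assert sorted(finite) == pytest.approx(sorted(roots), abs=1e-7)
            if fs.kind == "interval":
                assert inside[20000] == fs.contains(0.0)

    def test_point_estimate_inside_finite_interval(self, rng):
        for _ in range(50):
            bx = rng.uniform(0.08, 0.2) * rng.choice([-1, 1])
            by = rng.normal(0, 0.03)
            fs = fieller_interval(bx, 0.013, by, 0.02)
            if fs.kind == "interval":
                assert fs.low <= by / bx <= fs.high


class TestIVWFixed:
    def test_single_snp_reduces_to_wald(self):
        h = HarmonizedTable.from_arrays([0.1], [0.013], [0.03], [0.02])
        est = ivw_fixed(h)
        assert est.estimate == pytest.approx(0.3)
        assert est.se == pytest.approx(0.02 / 0.1)

    def test_zero_outcome_effects_give_zero(self):
        h = HarmonizedTable.from_arrays([0.1, 0.2], [0.01, 0.01], [0.0, 0.0], [0.02, 0.02])
        assert ivw_fixed(h).estimate == 0.0

    def test_matches_through_origin_wls_oracle(self, rng):
        for _ in range(100):
            h = make_harmonized(rng, int(rng.integers(3, 12)))
            fit = sm.WLS(h.beta_y, h.beta_x, weights=1 / h.se_y**2).fit()
            est = ivw_fixed(h)
            assert est.estimate == pytest.approx(fit.params[0], rel=1e-10)

    def test_rejects_zero_beta_x(self):
        h = HarmonizedTable.from_arrays([0.1, 0.0], [0.01, 0.01], [0.02, 0.01], [0.02, 0.02])
        with pytest.raises(ZeroDivisionError):
            ivw_fixed(h)


class TestIVWCorrelated:
    def test_identity_equals_fixed(self, rng):
        h = make_harmonized(rng, 8)
        fixed = ivw_fixed(h)
        gls = ivw_correlated(h, np.eye(8))
        assert gls.estimate == pytest.approx(fixed.estimate, rel=1e-12)
        assert gls.se == pytest.approx(fixed.se, rel=1e-12)

    def test_duplicate_snps_not_double_counted(self):
        single = HarmonizedTable.from_arrays([0.1], [0.013], [0.03], [0.02])
        dup = HarmonizedTable.from_arrays([0.1, 0.1], [0.013, 0.013], [0.03, 0.03],
                                          [0.02, 0.02])
        r = 1 - 1e-8
        est = ivw_correlated(dup, np.array([[1.0, r], [r, 1.0]]))
        ref = ivw_fixed(single)
        assert est.estimate == pytest.approx(ref.estimate, rel=1e-4)
        assert est.se >= ref.se * (1 - 1e-4)

    def test_matches_extended_precision_matrix_oracle(self, rng):
        for _ in range(100):
            m = 6
            h = make_harmonized(rng, m)
            raw = rng.normal(0, 1, (m, m + 4))
            cov = raw @ raw.T
            d = np.sqrt(np.diag(cov))
            rho = cov / np.outer(d, d)
            bx = h.beta_x.astype(np.longdouble)
            by = h.beta_y.astype(np.longdouble)
            omega = np.outer(h.se_y, h.se_y).astype(np.longdouble) * rho.astype(np.longdouble)
            oinv = np.linalg.inv(omega.astype(float)).astype(np.longdouble)
            denom = bx @ oinv @ bx
            expected = float((bx @ oinv @ by) / denom)
            est = ivw_correlated(h, rho)
            assert est.estimate == pytest.approx(expected, rel=1e-8)
            assert est.se == pytest.approx(float(1 / np.sqrt(denom)), rel=1e-8)

    def test_non_positive_definite_named(self):
        h = make_harmonized(np.random.default_rng(0), 2)
        rho = np.array([[1.0, 1.1], [1.1, 1.0]])
        with pytest.raises(np.linalg.LinAlgError, match="eigenvalue"):
            ivw_correlated(h, rho)


class TestWeightedMedian:
    def test_equal_weights_is_plain_median(self):
        h = HarmonizedTable.from_arrays([1.0, 1.0, 1.0], [1e-6] * 3,
                                        [0.1, 0.2, 0.9], [0.05] * 3)
        est = weighted_median(h, n_boot=10, seed=1)
        assert est.estimate == pytest.approx(0.2)

    def test_dominant_weight_breakdown_limit(self):
        # middle variant carries nearly all weight: tiny se_y
        h = HarmonizedTable.from_arrays([1.0, 1.0, 1.0], [1e-8] * 3,
                                        [0.1, 0.55, 0.9], [1.0, 1e-4, 1.0])
        est = weighted_median(h, n_boot=10, seed=1)
        assert est.estimate == pytest.approx(0.55, abs=1e-3)

    def test_refuses_fewer_than_three(self):
        h = HarmonizedTable.from_arrays([0.1, 0.2], [0.01] * 2, [0.02, 0.04], [0.02] * 2)
        with pytest.raises(ValueError, match=">= 3"):
            weighted_median(h, seed=0)

    def test_matches_cdf_scan_oracle(self, rng):
        for _ in range(100):
            h = make_harmonized(rng, 10)
            est = weighted_median(h, n_boot=2, seed=0).estimate
            ratios = h.beta_y / h.beta_x
            w = h.beta_x**2 / (h.se_y**2 + ratios**2 * h.se_x**2)
            w = w / w.sum()
            order = np.argsort(ratios)
            r, w = ratios[order], w[order]
            cum = np.cumsum(w) - w / 2
            # brute force: scan a fine grid of the piecewise-linear weighted CDF
            grid = np.linspace(r[0], r[-1], 200001)
            cdf = np.interp(grid, r, cum)
            oracle = grid[np.argmin(np.abs(cdf - 0.5))]
            assert est == pytest.approx(oracle, abs=(r[-1] - r[0]) / 100000)

    def test_bootstrap_se_reproducible(self, rng):
        h = make_harmonized(rng, 8)
        a = weighted_median(h, n_boot=200, seed=42)
        b = weighted_median(h, n_boot=200, seed=42)
        assert a.se == b.se


class TestMREgger:
    def test_noiseless_exact_recovery(self):
        bx = np.array([0.05, 0.08, 0.11, 0.15, 0.2])
        by = 0.3 * bx + 0.02
        h = HarmonizedTable.from_arrays(bx, [0.01] * 5, by, [0.02] * 5)
        slope, intercept = mr_egger(h)
        assert slope.estimate == pytest.approx(0.3, abs=1e-12)
        assert intercept.estimate == pytest.approx(0.02, abs=1e-12)

    def test_matches_wls_normal_equations_oracle(self, rng):
        for _ in range(100):
            h = make_harmonized(rng, int(rng.integers(4, 12)))
            sign = np.sign(h.beta_x)
            X = sm.add_constant(h.beta_x * sign)
            fit = sm.WLS(h.beta_y * sign, X, weights=1 / h.se_y**2).fit()
            slope, intercept = mr_egger(h)
            assert slope.estimate == pytest.approx(fit.params[1], rel=1e-10)
            assert intercept.estimate == pytest.approx(fit.params[0], rel=1e-10, abs=1e-14)

    def test_invariant_to_per_snp_allele_flips(self, rng):
        h = make_harmonized(rng, 9)
        flip = rng.choice([-1.0, 1.0], 9)
        h2 = HarmonizedTable.from_arrays(h.beta_x * flip, h.se_x, h.beta_y * flip, h.se_y)
        s1, i1 = mr_egger(h)
        s2, i2 = mr_egger(h2)
        assert s1.estimate == pytest.approx(s2.estimate)
        assert i1.estimate == pytest.approx(i2.estimate)

    def test_singular_design_raises(self):
        h = HarmonizedTable.from_arrays([0.1, 0.1, -0.1], [0.01] * 3,
                                        [0.02, 0.03, 0.01], [0.02] * 3)
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            mr_egger(h)

    def test_needs_three_snps(self):
        h = HarmonizedTable.from_arrays([0.1, 0.2], [0.01] * 2, [0.02, 0.04], [0.02] * 2)
        with pytest.raises(ValueError):
            mr_egger(h)


class TestCochranQ:
    def test_identical_ratios_give_zero(self):
        bx = np.array([0.1, 0.2, 0.4])
        h = HarmonizedTable.from_arrays(bx, [0.01] * 3, 0.3 * bx, [0.02] * 3)
        het = cochran_q(h)
        assert het.Q == pytest.approx(0.0, abs=1e-20)
        assert het.pvalue == pytest.approx(1.0)
        assert het.df == 2

    def test_two_snp_closed_form(self):
        # equal weights w, ratios differing by d: Q = w d^2 / 2
        bx, sy = 0.1, 0.02
        h = HarmonizedTable.from_arrays([bx, bx], [0.0, 0.0], [0.03, 0.05], [sy, sy])
        w = bx**2 / sy**2
        d = (0.05 - 0.03) / bx
        assert cochran_q(h).Q == pytest.approx(w * d**2 / 2)


class TestEquivariance:
    def test_scaling_outcome_scales_every_estimate(self, rng):
        h = make_harmonized(rng, 8)
        c = 3.7
        hc = HarmonizedTable.from_arrays(h.beta_x, h.se_x, c * h.beta_y, c * h.se_y)
        assert ivw_fixed(hc).estimate == pytest.approx(c * ivw_fixed(h).estimate)
        assert (weighted_median(hc, 50, seed=2).estimate
                == pytest.approx(c * weighted_median(h, 50, seed=2).estimate))
        assert mr_egger(hc)[0].estimate == pytest.approx(c * mr_egger(h)[0].estimate)

    def test_flipping_exposure_flips_sign(self, rng):
        h = make_harmonized(rng, 8)
        hf = HarmonizedTable.from_arrays(-h.beta_x, h.se_x, h.beta_y, h.se_y)
        assert ivw_fixed(hf).estimate == pytest.approx(-ivw_fixed(h).estimate)
        assert mr_egger(hf)[0].estimate == pytest.approx(-mr_egger(h)[0].estimate)
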