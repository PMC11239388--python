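import numpy as np
import pytest

from mrkit.exceptions import InsufficientInstrumentsError
from mrkit.estimators import (
    _ivw_fit,
    ivw,
    mode_based,
    mr_egger,
    wald_ratio,
    weighted_median,
)
from mrkit.harmonize import HarmonizedSet
from conftest import random_harmonized
from oracles import kernel_mode_grid, weighted_median_scan, wls_intercept, wls_origin


def hset(bx, by, sy, sx=None):
    bx = np.asarray(bx, float)
    sx = np.full_like(bx, 0.001) if sx is None else np.asarray(sx, float)
    return HarmonizedSet.from_arrays(bx, sx, by, sy)


class TestWaldRatio:
    def test_direct_division(self):
        est = wald_ratio(0.1, 0.05, 0.01)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_sign_propagation_keeps_se_positive(self):
        est = wald_ratio(-0.1, 0.05, 0.01)
        assert est.beta == pytest.approx(-0.5)
        assert est.se == pytest.approx(0.1)

    def test_null_numerator_gives_p_of_one(self):
        est = wald_ratio(0.2, 0.0, 0.02)
        assert est.beta == 0.0
        assert est.pval == pytest.approx(1.0)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.05, 0.01)


class TestIvw:
    def test_consensus_ratios_recovered_exactly(self):
        bx = np.array([0.1, 0.2, 0.05])
        h = hset(bx, 0.5 * bx, [0.01, 0.03, 0.02])
        assert ivw(h).beta == pytest.approx(0.5, rel=1e-12)

    def test_single_snp_fit_equals_wald_ratio(self):
        # precondition n >= 2 relaxed by calling the internal fit directly
        beta, se, _ = _ivw_fit(np.array([0.1]), np.array([0.05]), np.array([0.01]))
        w = wald_ratio(0.1, 0.05, 0.01)
        assert beta == pytest.approx(w.beta, rel=1e-12)
        assert se == pytest.approx(w.se, rel=1e-12)

    def test_requires_two_pairs(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw(hset([0.1], [0.05], [0.01]))

    def test_matches_generic_wls_oracle(self, rng):
        h = random_harmonized(rng, 5, ratio=0.4, noise=0.02)
        bx = h.pairs.beta_exp.to_numpy()
        by = h.pairs.beta_out.to_numpy()
        sy = h.pairs.se_out.to_numpy()
        b_o, se_o, scale_o = wls_origin(bx, by, 1 / sy**2)
        fixed = ivw(h, re_mode="fixed")
        assert fixed.beta == pytest.approx(b_o, rel=1e-10)
        assert fixed.se == pytest.approx(se_o, rel=1e-10)
        mre = ivw(h, re_mode="multiplicative_random")
        assert mre.se == pytest.approx(se_o * max(1, scale_o**0.5), rel=1e-10)

    def test_estimate_lies_within_ratio_range(self, rng):
        for _ in range(10):
            h = random_harmonized(rng, 8, ratio=0.3, noise=0.05)
            r = h.pairs.beta_out / h.pairs.beta_exp
            assert r.min() - 1e-12 <= ivw(h).beta <= r.max() + 1e-12


class TestEgger:
    def test_exact_linear_fit_recovers_slope_and_intercept(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2])
        h = hset(bx, 0.02 + 0.5 * bx, [0.01] * 4)
        res = mr_egger(h)
        assert res.slope.beta == pytest.approx(0.5, rel=1e-10)
        assert res.intercept == pytest.approx(0.02, rel=1e-10)

    def test_no_pleiotropy_zero_residual_limit(self):
        bx = np.array([0.05, 0.1, 0.15])
        h = hset(bx, 0.5 * bx, [0.01] * 3)
        res = mr_egger(h)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.intercept_pval == pytest.approx(1.0)

    def test_matches_generic_wls_with_intercept_oracle(self, rng):
        h = random_harmonized(rng, 6, ratio=0.4, noise=0.03)
        bx = h.pairs.beta_exp.to_numpy()
        by = h.pairs.beta_out.to_numpy()
        sy = h.pairs.se_out.to_numpy()
        sign = np.where(bx < 0, -1, 1)
        b0, b1, se0, se1, scale = wls_intercept(bx * sign, by * sign, 1 / sy**2)
        infl = max(1, scale**0.5)
        res = mr_egger(h)
        assert res.slope.beta == pytest.approx(b1, rel=1e-9)
        assert res.intercept == pytest.approx(b0, rel=1e-9)
        assert res.slope.se == pytest.approx(se1 * infl, rel=1e-9)
        assert res.intercept_se == pytest.approx(se0 * infl, rel=1e-9)

    def test_requires_three_pairs(self):
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(hset([0.1, 0.2], [0.05, 0.1], [0.01, 0.01]))


class TestWeightedMedian:
    def test_equal_weights_plain_median(self):
        bx = np.array([0.1, 0.1, 0.1])
        by = np.array([0.01, 0.05, 0.09])  # ratios 0.1, 0.5, 0.9
        h = hset(bx, by, [0.01] * 3)
        est = weighted_median(h, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.5)

    def test_consensus_bootstrap_se_shrinks_with_precision(self):
        bx = np.array([0.1, 0.2, 0.3])
        h_noisy = hset(bx, 0.5 * bx, [0.02] * 3, sx=[0.02] * 3)
        h_tight = hset(bx, 0.5 * bx, [1e-5] * 3, sx=[1e-5] * 3)
        se_noisy = weighted_median(h_noisy, n_boot=200, seed=2).se
        se_tight = weighted_median(h_tight, n_boot=200, seed=2).se
        assert weighted_median(h_tight, n_boot=200, seed=2).beta == pytest.approx(0.5)
        assert se_tight < se_noisy / 100

    def test_matches_exhaustive_interpolation_oracle(self, rng):
        h = random_harmonized(rng, 7, ratio=0.6, noise=0.05)
        bx = h.pairs.beta_exp.to_numpy()
        by = h.pairs.beta_out.to_numpy()
        sy = h.pairs.se_out.to_numpy()
        expect = weighted_median_scan(by / bx, bx**2 / sy**2)
        est = weighted_median(h, n_boot=10, seed=3)
        assert est.beta == pytest.approx(expect, rel=1e-12)

    def test_estimate_lies_within_ratio_range(self, rng):
        h = random_harmonized(rng, 9, ratio=0.2, noise=0.05)
        r = h.pairs.beta_out / h.pairs.beta_exp
        est = weighted_median(h, n_boot=10, seed=4)
        assert r.min() - 1e-12 <= est.beta <= r.max() + 1e-12

    def test_identical_seed_identical_se_different_seed_close(self):
        rng = np.random.default_rng(7)
        h = random_harmonized(rng, 10, ratio=0.5, noise=0.02)
        a = weighted_median(h, n_boot=400, seed=11)
        b = weighted_median(h, n_boot=400, seed=11)
        c = weighted_median(h, n_boot=400, seed=12)
        assert a.se == b.se
        # bootstrap-SE Monte-Carlo error ~ se / sqrt(2 (B - 1))
        mc = a.se / np.sqrt(2 * 399)
        assert abs(a.se - c.se) < 3 * mc + 1e-12


class TestModeBased:
    def test_majority_cluster_wins(self):
        bx = np.array([0.1, 0.1, 0.1, 0.1])
        by = np.array([0.05, 0.05, 0.05, 0.2])  # ratios 0.5 x3, 2.0
        h = hset(bx, by, [0.01] * 4)
        est = mode_based(h, variant="simple", n_boot=10, seed=5)
        assert est.beta == pytest.approx(0.5, abs=0.05)

    def test_single_atom_returned_exactly(self):
        bx = np.array([0.1, 0.2, 0.4])
        h = hset(bx, 0.7 * bx, [0.01] * 3)
        for phi in (0.5, 1.0, 3.0):
            est = mode_based(h, variant="simple", bandwidth_phi=phi, n_boot=10, seed=6)
            assert est.beta == pytest.approx(0.7, rel=1e-12)

    def test_weighted_equals_simple_under_equal_weights(self):
        bx = np.array([0.1, 0.1, 0.1, 0.1])
        by = np.array([0.03, 0.05, 0.06, 0.11])
        h = hset(bx, by, [0.01] * 4)
        w = mode_based(h, variant="weighted", n_boot=10, seed=7)
        s = mode_based(h, variant="simple", n_boot=10, seed=7)
        assert w.beta == pytest.approx(s.beta, rel=1e-12)

    def test_matches_dense_grid_oracle(self, rng):
        from mrkit.estimators import _mode_bandwidth
        h = random_harmonized(rng, 12, ratio=0.5, noise=0.1)
        bx = h.pairs.beta_exp.to_numpy()
        by = h.pairs.beta_out.to_numpy()
        sy = h.pairs.se_out.to_numpy()
        r = by / bx
        w = bx**2 / sy**2
        bw = _mode_bandwidth(r, 1.0)
        expect = kernel_mode_grid(r, w / w.sum(), bw)
        est = mode_based(h, variant="weighted", n_boot=10, seed=8)
        assert est.beta == pytest.approx(expect, abs=2 * bw / 2048 + 1e-6)


class TestInvariances:
    @pytest.mark.parametrize("c", [2.0, 0.1])
    def test_outcome_scale_equivariance(self, rng, c):
        h = random_harmonized(rng, 8, ratio=0.4, noise=0.02)
        scaled = HarmonizedSet.from_arrays(
            h.pairs.beta_exp, h.pairs.se_exp,
            c * h.pairs.beta_out, c * h.pairs.se_out,
        )
        for est_fn in (
            lambda x: ivw(x),
            lambda x: mr_egger(x).slope,
            lambda x: weighted_median(x, n_boot=50, seed=9),
            lambda x: mode_based(x, n_boot=50, seed=9),
        ):
            a, b = est_fn(h), est_fn(scaled)
            assert b.beta == pytest.approx(c * a.beta, rel=1e-7)
            assert b.se == pytest.approx(c * a.se, rel=1e-7)

    @pytest.mark.parametrize("c", [3.0])
    def test_exposure_unit_change_divides_estimate(self, rng, c):
        h = random_harmonized(rng, 8, ratio=0.4, noise=0.02)
        scaled = HarmonizedSet.from_arrays(
            c * h.pairs.beta_exp, c * h.pairs.se_exp,
            h.pairs.beta_out, h.pairs.se_out,
        )
        assert ivw(scaled).beta == pytest.approx(ivw(h).beta / c, rel=1e-9)
        assert mr_egger(scaled).slope.beta == pytest.approx(
            mr_egger(h).slope.beta / c, rel=1e-9
        )
        wm_h = weighted_median(h, n_boot=10, seed=10)
        wm_s = weighted_median(scaled, n_boot=10, seed=10)
        assert wm_s.beta == pytest.approx(wm_h.beta / c, rel=1e-9)


def test_all_estimators_converge_to_truth_as_noise_shrinks(rng):
    """Pleiotropy-free data, strong instruments: every method approaches the
    true effect, and faster at the lower noise level."""
    truth = 0.3
    for scale, tol in ((1.0, 0.15), (0.1, 0.015)):
        bx = rng.uniform(0.05, 0.2, 30)
        sx = np.full(30, 0.002 * scale)
        sy = np.full(30, 0.01 * scale)
        by = truth * bx + rng.normal(0, sy)
        h = HarmonizedSet.from_arrays(bx + rng.normal(0, sx), sx, by, sy)
        ests = [
            ivw(h).beta,
            mr_egger(h).slope.beta,
            weighted_median(h, n_boot=50, seed=13).beta,
            mode_based(h, "weighted", n_boot=50, seed=13).beta,
            mode_based(h, "simple", n_boot=50, seed=13).beta,
        ]
        assert all(abs(e - truth) < tol for e in ests)
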