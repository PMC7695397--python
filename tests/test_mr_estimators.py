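"""Univariable estimators: closed forms, oracle equivalences, simulations."""

import numpy as np
import pytest
from scipy import stats

import mrkit
from mrkit.mr_estimators import (EstimationError, _weighted_median_point,
                                 ivw_fixed_effects, maximum_likelihood, mr_egger,
                                 weighted_median)
from mrkit.synthetic_data import SimConfig, simulate_dataset


def random_instance(rng, J=20):
    bx = rng.normal(0, 0.1, J)
    sx = rng.uniform(0.001, 0.01, J)
    by = 0.3 * bx + rng.normal(0, 0.02, J)
    sy = rng.uniform(0.005, 0.05, J)
    return bx, sx, by, sy


def noiseless_dataset(seed=1, J=60):
    cfg = SimConfig(n_snps=J, n_exposures=1, theta=(0.5,), n_exp=10**16, n_out=10**16,
                    exposure_effect_scale=0.2, pleiotropy_frac=0.0, decoy_frac=0.0,
                    palindromic_frac=0.0, flip_frac=0.0, seed=seed)
    (exp,), out, _ = simulate_dataset(cfg)
    bx = np.array([r.beta for r in exp])
    sx = np.array([r.se for r in exp])
    by = np.array([r.beta for r in out])
    sy = np.array([r.se for r in out])
    return bx, sx, by, sy


class TestIvw:
    def test_single_snp_ratio(self):
        est = ivw_fixed_effects([0.1], [0.0], [0.05], [0.01])
        assert est.beta == pytest.approx(0.5)

    def test_two_snp_closed_form(self):
        est = ivw_fixed_effects([1.0, 1.0], [0, 0], [2.0, 4.0], [1.0, 1.0])
        assert est.beta == pytest.approx(3.0)
        assert est.se == pytest.approx(1.0 / np.sqrt(2.0))

    def test_equals_wls_through_origin(self):
        """IVW == weights-1/sy² least squares of by on bx with no intercept."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            bx, sx, by, sy = random_instance(rng)
            est = ivw_fixed_effects(bx, sx, by, sy)
            X = (bx / sy)[:, None]
            coef = np.linalg.lstsq(X, by / sy, rcond=None)[0][0]
            assert est.beta == pytest.approx(coef, abs=1e-12)

    def test_convex_combination_of_ratios(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            bx, sx, by, sy = random_instance(rng)
            ratios = by / bx
            est = ivw_fixed_effects(bx, sx, by, sy)
            assert ratios.min() - 1e-12 <= est.beta <= ratios.max() + 1e-12

    def test_adding_larger_ratio_increases_estimate(self):
        bx, sx, by, sy = [0.1, 0.2], [0, 0], [0.05, 0.1], [0.01, 0.01]
        base = ivw_fixed_effects(bx, sx, by, sy).beta
        grown = ivw_fixed_effects(bx + [0.1], sx + [0], by + [0.2], sy + [0.01]).beta
        assert grown > base

    def test_degenerate_inputs_fatal(self):
        with pytest.raises(EstimationError):
            ivw_fixed_effects([], [], [], [])
        with pytest.raises(EstimationError):
            ivw_fixed_effects([0.0, 0.0], [0, 0], [0.1, 0.1], [0.01, 0.01])

    def test_or_ci_consistent(self):
        est = ivw_fixed_effects([0.1, 0.2], [0, 0], [0.05, 0.1], [0.01, 0.02])
        assert est.or_ == pytest.approx(np.exp(est.beta))
        assert est.or_lci95 <= est.or_ <= est.or_uci95
        assert est.or_lci95 == pytest.approx(np.exp(est.beta - 1.959964 * est.se))


class TestIvwRandomEffects:
    def test_overdispersion_widens_se_never_narrows(self):
        rng = np.random.default_rng(21)
        bx = rng.normal(0, 0.1, 30)
        sy = np.full(30, 0.01)
        by = 0.3 * bx + rng.normal(0, 0.05, 30)  # strong heterogeneity
        fe = mrkit.ivw(bx, np.zeros(30), by, sy)
        re = mrkit.ivw(bx, np.zeros(30), by, sy, random_effects=True)
        assert re.beta == pytest.approx(fe.beta)  # point estimate unchanged
        assert re.se > fe.se
        # homogeneous data: scaling floored at 1, SEs coincide
        by_h = 0.3 * bx + rng.normal(0, 0.001, 30)
        assert mrkit.ivw(bx, np.zeros(30), by_h, sy, random_effects=True).se == \
            pytest.approx(mrkit.ivw(bx, np.zeros(30), by_h, sy).se)


class TestMaximumLikelihood:
    def test_sx_zero_limit_equals_ivw(self):
        rng = np.random.default_rng(2)
        bx, _, by, sy = random_instance(rng)
        ml = maximum_likelihood(bx, np.zeros_like(bx), by, sy)
        ivw = ivw_fixed_effects(bx, np.zeros_like(bx), by, sy)
        assert ml.beta == pytest.approx(ivw.beta, abs=1e-6)
        assert ml.se == pytest.approx(ivw.se, rel=1e-4)

    def test_null_type_i_error(self):
        """theta=0, J=50: rejection rate at 0.05 within binomial 99% bounds."""
        rng = np.random.default_rng(3)
        J, reps = 50, 1000
        rejections = 0
        for _ in range(reps):
            b_true = rng.normal(0, 0.1, J)
            sx = np.full(J, 0.01)
            sy = np.full(J, 0.02)
            bx = b_true + rng.normal(0, sx)
            by = rng.normal(0, sy)  # theta = 0
            rejections += maximum_likelihood(bx, sx, by, sy).pval < 0.05
        bound = 2.576 * np.sqrt(0.05 * 0.95 / reps)
        assert abs(rejections / reps - 0.05) < bound

    def test_accounts_for_exposure_noise(self):
        """With noisy bx, ML corrects the attenuation IVW suffers."""
        rng = np.random.default_rng(4)
        J = 4000
        b_true = rng.normal(0, 0.05, J)
        sx = np.full(J, 0.05)  # exposure noise comparable to spread
        sy = np.full(J, 0.01)
        bx = b_true + rng.normal(0, sx)
        by = 0.5 * b_true + rng.normal(0, sy)
        ml = maximum_likelihood(bx, sx, by, sy).beta
        ivw = ivw_fixed_effects(bx, sx, by, sy).beta
        assert abs(ml - 0.5) < abs(ivw - 0.5)


class TestWeightedMedian:
    def test_equal_weights_plain_median(self):
        assert _weighted_median_point(np.array([1.0, 2.0, 3.0]),
                                      np.ones(3)) == pytest.approx(2.0)

    def test_interpolation_hand_case(self):
        """ratios (1,2,3), weights (0.6,0.2,0.2): breakpoints p=(0.3,0.7,0.9),
        interpolating to p=0.5 gives 1.5."""
        got = _weighted_median_point(np.array([1.0, 2.0, 3.0]),
                                     np.array([0.6, 0.2, 0.2]))
        assert got == pytest.approx(1.5)

    def test_interpolation_matches_grid_oracle(self):
        """Estimate agrees with a dense grid search for the 0.5 crossing of
        the piecewise-linear cumulative-weight curve."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            r = np.sort(rng.normal(0, 1, 9))
            w = rng.uniform(0.1, 1, 9)
            got = _weighted_median_point(r, w)
            order = np.argsort(r)
            p = np.cumsum(w[order]) / w.sum() - (w[order] / w.sum()) / 2
            grid = np.linspace(r.min(), r.max(), 20001)
            crossing = grid[np.argmin(np.abs(np.interp(grid, r[order], p) - 0.5))]
            assert got == pytest.approx(crossing, abs=2e-3)

    def test_weights_depend_on_bx_and_sy(self):
        est = weighted_median([0.1, 0.2, 0.3], [0, 0, 0], [0.05, 0.1, 0.15],
                              [0.01, 0.01, 0.01], n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.5)

    def test_bootstrap_se_reproducible_and_positive(self):
        rng = np.random.default_rng(6)
        bx, sx, by, sy = random_instance(rng, J=15)
        a = weighted_median(bx, sx, by, sy, n_boot=200, seed=42)
        b = weighted_median(bx, sx, by, sy, n_boot=200, seed=42)
        assert a.se == b.se > 0

    def test_zero_bx_excluded_with_warning(self, caplog):
        est = weighted_median([0.0, 0.1, 0.2, 0.3], [0] * 4,
                              [0.0, 0.05, 0.1, 0.15], [0.01] * 4, n_boot=50, seed=0)
        assert est.n_snp == 3
        assert "excluding" in caplog.text
        with pytest.raises(EstimationError):
            weighted_median([0.0, 0.1, 0.2], [0] * 3, [0.0, 0.05, 0.1], [0.01] * 3)


class TestMrEgger:
    def test_exact_fit_zero_intercept(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        res = mr_egger(bx, np.zeros(5), 2.0 * bx, np.full(5, 0.01))
        assert res.slope.beta == pytest.approx(2.0, abs=1e-10)
        assert res.intercept == pytest.approx(0.0, abs=1e-10)
        assert res.intercept_pval > 0.99

    def test_reorientation_sign_invariance(self):
        """Estimates are invariant to the input allele orientation because
        SNPs are re-signed to bx >= 0 before the regression."""
        rng = np.random.default_rng(7)
        bx, sx, by, sy = random_instance(rng, J=12)
        flip = rng.random(12) < 0.5
        res_a = mr_egger(bx, sx, by, sy)
        res_b = mr_egger(np.where(flip, -bx, bx), sx, np.where(flip, -by, by), sy)
        assert res_a.slope.beta == pytest.approx(res_b.slope.beta, abs=1e-12)
        assert res_a.intercept == pytest.approx(res_b.intercept, abs=1e-12)

    def test_matches_statsmodels_free_fit(self):
        """Intercept/slope/SEs equal a hand-built weighted normal-equations fit."""
        rng = np.random.default_rng(8)
        bx, sx, by, sy = random_instance(rng, J=15)
        res = mr_egger(bx, sx, by, sy)
        sign = np.where(bx < 0, -1.0, 1.0)
        X = np.column_stack([np.ones(15), bx * sign])
        W = np.diag(sy**-2.0)
        beta_hat = np.linalg.solve(X.T @ W @ X, X.T @ W @ (by * sign))
        resid = by * sign - X @ beta_hat
        s2 = float(resid @ W @ resid) / (15 - 2)
        cov = s2 * np.linalg.inv(X.T @ W @ X)
        assert res.intercept == pytest.approx(beta_hat[0], abs=1e-10)
        assert res.slope.beta == pytest.approx(beta_hat[1], abs=1e-10)
        assert res.intercept_se == pytest.approx(np.sqrt(cov[0, 0]), rel=1e-8)

    def test_no_spread_fatal(self):
        with pytest.raises(EstimationError, match="spread"):
            mr_egger([0.1, 0.1, -0.1], [0] * 3, [0.05, 0.05, -0.05], [0.01] * 3)


class TestCrossEstimatorProperties:
    def test_sign_equivariance(self):
        rng = np.random.default_rng(9)
        bx, sx, by, sy = random_instance(rng, J=12)
        for fn, kwargs in ((ivw_fixed_effects, {}), (maximum_likelihood, {}),
                           (weighted_median, {"n_boot": 100, "seed": 0})):
            pos = fn(bx, sx, by, sy, **kwargs).beta
            neg = fn(bx, sx, -by, sy, **kwargs).beta
            assert neg == pytest.approx(-pos, abs=1e-9)
        assert mr_egger(bx, sx, -by, sy).slope.beta == pytest.approx(
            -mr_egger(bx, sx, by, sy).slope.beta, abs=1e-12)

    def test_noiseless_recovery_all_estimators(self):
        """At essentially infinite GWAS sample size every estimator returns
        the generating causal effect to 1e-6."""
        bx, sx, by, sy = noiseless_dataset()
        assert ivw_fixed_effects(bx, sx, by, sy).beta == pytest.approx(0.5, abs=1e-6)
        assert maximum_likelihood(bx, sx, by, sy).beta == pytest.approx(0.5, abs=1e-6)
        assert weighted_median(bx, sx, by, sy, n_boot=50, seed=0).beta == pytest.approx(
            0.5, abs=1e-6)
        assert mr_egger(bx, sx, by, sy).slope.beta == pytest.approx(0.5, abs=1e-6)
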