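"""The eight pleiotropy-robust MR estimators: worked examples, independent
numerical oracles and shared invariants (consensus, equivariance,
null calibration)."""

import numpy as np
import pytest
from scipy import optimize, stats

import mrselect.estimators as E
from mrselect.estimators import (
    DivisionDegeneracyError,
    InsufficientInstrumentsError,
    conmix,
    estimate_all,
    ivw,
    mbe,
    mr_egger,
    mr_lasso,
    mr_raps,
    mr_robust,
    ratio_estimates,
    weighted_median,
)

from conftest import make_summary, simulate_summary


# ---------------------------------------------------------------------------
# ratio building block


class TestRatioEstimates:
    def test_elementwise_ratios(self):
        s = make_summary([0.1, 0.2], [0.02, 0.04])
        r = ratio_estimates(s)
        np.testing.assert_allclose(r.ratios, [0.2, 0.2])

    def test_zero_beta_x_errors_naming_snp(self):
        s = make_summary([0.1, 0.0], [0.02, 0.04])
        with pytest.raises(DivisionDegeneracyError, match="snp_1"):
            ratio_estimates(s)

    def test_first_order_weight(self):
        s = make_summary([0.1], [0.05], se_y=[0.01])
        assert ratio_estimates(s).weights[0] == pytest.approx(100.0)


# ---------------------------------------------------------------------------
# regression-based methods


class TestIVW:
    def test_hand_computed_weighted_sums(self):
        s = make_summary([0.1, 0.2, 0.3], [0.02, 0.04, 0.09], se_y=[0.1, 0.1, 0.1])
        est = ivw(s)
        assert est.theta_hat == pytest.approx(0.037 / 0.14, rel=1e-12)

    def test_identical_ratios_fixed_effect_se(self):
        s = make_summary([0.1, 0.2, 0.3], [0.03, 0.06, 0.09], se_y=[0.1, 0.1, 0.1])
        est = ivw(s)
        assert est.theta_hat == pytest.approx(0.3, rel=1e-12)
        assert est.extras["residual_scale"] == 1.0  # floored: never below fixed-effect
        assert est.se == pytest.approx(est.extras["se_fixed"], rel=1e-12)

    def test_single_snp_errors(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw(make_summary([0.1], [0.02]))

    def test_matches_weighted_normal_equations(self, rng):
        """Brute-force weighted least squares through the origin oracle."""
        s = simulate_summary(rng, J=12, theta=0.2)
        w = 1.0 / s.se_y**2
        oracle = float(np.sum(w * s.beta_x * s.beta_y) / np.sum(w * s.beta_x**2))
        assert ivw(s).theta_hat == pytest.approx(oracle, abs=1e-10)


class TestEgger:
    def test_exact_line_with_intercept(self):
        s = make_summary([1.0, 2.0, 3.0], [0.7, 0.9, 1.1], se_y=[0.1, 0.1, 0.1])
        est = mr_egger(s)
        assert est.theta_hat == pytest.approx(0.2, rel=1e-10)
        assert est.extras["intercept"] == pytest.approx(0.5, rel=1e-10)

    def test_line_through_origin_reduces_to_ivw(self):
        s = make_summary([1.0, 2.0, 3.0], [0.2, 0.4, 0.6], se_y=[0.1, 0.2, 0.3])
        est = mr_egger(s)
        assert est.extras["intercept"] == pytest.approx(0.0, abs=1e-12)
        assert est.theta_hat == pytest.approx(0.2, rel=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        """Random 5-SNP set vs an independent weighted linear-algebra solve."""
        s = simulate_summary(rng, J=5, theta=0.1)
        sign = np.where(s.beta_x < 0, -1.0, 1.0)
        bx, by = sign * s.beta_x, sign * s.beta_y
        sw = np.sqrt(1.0 / s.se_y**2)
        A = np.column_stack([np.ones(5) * sw, bx * sw])
        coef, *_ = np.linalg.lstsq(A, by * sw, rcond=None)
        est = mr_egger(s)
        assert est.extras["intercept"] == pytest.approx(coef[0], abs=1e-10)
        assert est.theta_hat == pytest.approx(coef[1], abs=1e-10)

    def test_too_few_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(make_summary([0.1, 0.2], [0.01, 0.02]))


class TestRobust:
    def test_exact_line_unit_weights(self):
        s = make_summary([1.0, 2.0, 3.0, 4.0], [0.2, 0.4, 0.6, 0.8], se_y=[0.1] * 4)
        est = mr_robust(s)
        assert est.theta_hat == pytest.approx(0.2, rel=1e-10)
        np.testing.assert_allclose(est.extras["weights"], 1.0)

    def test_gross_outlier_downweighted(self, rng):
        bx = rng.uniform(0.1, 0.3, 10)
        by = 0.2 * bx + rng.normal(0, 0.001, 10)
        by[9] = 0.2 * bx[9] + 0.3  # gross pleiotropic outlier
        s = make_summary(bx, by, se_y=[0.01] * 10)
        est = mr_robust(s)
        w = 1.0 / s.se_y**2
        ols = float(np.sum(w * bx * by) / np.sum(w * bx**2))
        assert abs(est.theta_hat - 0.2) < 0.01
        assert abs(ols - 0.2) >= 0.05
        assert est.extras["weights"][9] < 0.1


class TestWeightedMedian:
    def test_interpolation_example(self):
        s = make_summary([1.0, 1.0, 1.0], [1.0, 2.0, 10.0], se_y=[1.0] * 3)
        est = weighted_median(s, n_boot=50, seed=1)
        assert est.theta_hat == pytest.approx(2.0, rel=1e-12)

    def test_all_equal_ratios(self):
        s = make_summary([0.1, 0.2, 0.3], [0.05, 0.1, 0.15], se_y=[0.01] * 3)
        est = weighted_median(s, n_boot=200, seed=2)
        assert est.theta_hat == pytest.approx(0.5, rel=1e-12)
        assert est.se < 0.2

    def test_weight_concentration_limit(self):
        bx = np.array([1.0, 0.01, 0.01])
        s = make_summary(bx, [0.7, 0.03, 0.05], se_y=[0.1] * 3)
        est = weighted_median(s, n_boot=50, seed=3)
        assert est.theta_hat == pytest.approx(0.7, abs=0.05)

    def test_matches_exhaustive_oracle(self, rng):
        """Independent cumulative-weight interpolation oracle."""
        s = simulate_summary(rng, J=15, theta=0.2)
        r = s.beta_y / s.beta_x
        w = s.beta_x**2 / s.se_y**2
        order = np.argsort(r)
        rs, ws = r[order], w[order]
        cum = np.cumsum(ws) - ws / 2.0
        p = cum / ws.sum()
        k = int(np.searchsorted(p, 0.5))
        oracle = rs[k - 1] + (rs[k] - rs[k - 1]) * (0.5 - p[k - 1]) / (p[k] - p[k - 1])
        est = weighted_median(s, n_boot=10, seed=4)
        assert est.theta_hat == pytest.approx(oracle, abs=1e-10)


class TestMBE:
    def test_all_equal_ratios(self):
        s = make_summary([0.1, 0.2, 0.4], [0.03, 0.06, 0.12], se_y=[0.01] * 3)
        est = mbe(s, n_boot=50, seed=5)
        assert est.theta_hat == pytest.approx(0.3, abs=1e-9)

    def test_dominant_mode(self):
        """Ratios {1,1,1,5} with equal weights: direct density evaluation
        puts the mode within grid resolution of 1."""
        bx = np.array([1.0, 1.0, 1.0, 1.0])
        by = np.array([1.0, 1.0, 1.0, 5.0])
        s = make_summary(bx, by, se_y=[1.0] * 4)
        est = mbe(s, phi=1.0, n_boot=50, seed=6)
        # independent direct evaluation on the same bandwidth
        from mrselect.estimators import _mbe_bandwidth

        h = _mbe_bandwidth(by / bx, 1.0)
        grid = np.linspace(-2, 8, 100_001)
        dens = sum(np.exp(-0.5 * ((grid - r) / h) ** 2) for r in by / bx)
        oracle = grid[np.argmax(dens)]
        assert est.theta_hat == pytest.approx(oracle, abs=0.02)
        assert abs(est.theta_hat - 1.0) < 0.05

    def test_large_bandwidth_moves_toward_weighted_mean(self):
        bx = np.ones(6)
        by = np.array([0.0, 0.05, 0.1, 0.9, 0.95, 1.0])
        s = make_summary(bx, by, se_y=[0.5] * 6)
        wmean = float(np.average(by / bx, weights=bx**2 / s.se_y**2))
        t1 = mbe(s, phi=1.0, n_boot=10, seed=7).theta_hat
        t10 = mbe(s, phi=10.0, n_boot=10, seed=7).theta_hat
        assert abs(t10 - wmean) < abs(t1 - wmean)


class TestConmix:
    def test_outlier_classified_invalid(self):
        bx = np.array([1.0, 1.0, 1.0, 1.0])
        by = np.array([0.2, 0.2, 0.2, 5.0])
        s = make_summary(bx, by, se_y=[0.05] * 4)
        est = conmix(s)
        assert est.theta_hat == pytest.approx(0.2, abs=0.02)
        assert not est.extras["valid_mask"][3]
        assert est.extras["valid_mask"][:3].all()

    def test_all_equal_tiny_se(self):
        s = make_summary([1.0, 1.0, 1.0], [0.3, 0.3, 0.3], se_y=[0.01] * 3)
        est = conmix(s)
        assert est.theta_hat == pytest.approx(0.3, abs=0.01)
        assert est.extras["valid_mask"].all()

    def test_matches_brute_force_likelihood(self, rng):
        """Straight-loop mixture log-likelihood over the same grid."""
        s = simulate_summary(rng, J=10, theta=0.2)
        est = conmix(s)
        r = s.beta_y / s.beta_x
        se_r = np.abs(s.se_y / s.beta_x)
        psi = est.extras["psi"]
        pad = 3.0 * se_r.max()
        grid = np.linspace(r.min() - pad, r.max() + pad, 5001)
        best_ll, best_th = -np.inf, None
        for th in grid:
            ll = 0.0
            for j in range(10):
                lv = stats.norm.logpdf(r[j], th, se_r[j])
                li = stats.norm.logpdf(r[j], 0.0, np.sqrt(se_r[j] ** 2 + psi**2))
                ll += max(lv, li)
            if ll > best_ll:
                best_ll, best_th = ll, th
        assert est.theta_hat == pytest.approx(best_th, abs=1e-9)

    def test_ci_stable_under_grid_refinement(self, rng):
        s = simulate_summary(rng, J=10, theta=0.0)
        est = conmix(s, n_grid=5001)
        fine = conmix(s, n_grid=50_001)
        r = s.beta_y / s.beta_x
        step = (r.max() - r.min() + 6 * np.max(np.abs(s.se_y / s.beta_x))) / 5000
        assert abs(est.extras["ci_lower"] - fine.extras["ci_lower"]) <= step
        assert abs(est.extras["ci_upper"] - fine.extras["ci_upper"]) <= step

    def test_grid_must_cover_ratios(self):
        s = make_summary([1.0, 1.0, 1.0], [0.0, 0.5, 1.0], se_y=[0.1] * 3)
        with pytest.raises(ValueError):
            conmix(s, grid=np.linspace(-0.1, 0.1, 100))


class TestRAPS:
    def test_reduces_to_fixed_effect_ivw(self):
        """With negligible exposure error, quadratic loss and no
        overdispersion the profile score is the IVW normal equation."""
        s = make_summary(
            [0.1, 0.2, 0.3], [0.02, 0.05, 0.08],
            se_x=[1e-10] * 3, se_y=[0.1, 0.15, 0.2],
        )
        est = mr_raps(s, loss="quadratic", overdispersion=False)
        w = 1.0 / s.se_y**2
        fe = float(np.sum(w * s.beta_x * s.beta_y) / np.sum(w * s.beta_x**2))
        assert est.theta_hat == pytest.approx(fe, abs=1e-8)
        assert est.se == pytest.approx(1.0 / np.sqrt(np.sum(w * s.beta_x**2)), rel=0.05)

    def test_null_recovery(self, rng):
        s = simulate_summary(rng, J=50, theta=0.0)
        est = mr_raps(s)
        assert abs(est.theta_hat) < 4.0 * est.se

    def test_root_matches_sign_change_scan(self, rng):
        """Fine-grid sign-change scan of the estimating equation."""
        s = simulate_summary(rng, J=20, theta=0.2)
        est = mr_raps(s, loss="huber", overdispersion=False)
        tau2 = 0.0

        def score(theta):
            sig2 = s.se_y**2 + theta**2 * s.se_x**2 + tau2
            t = (s.beta_y - theta * s.beta_x) / np.sqrt(sig2)
            psi = np.clip(t, -1.345, 1.345)
            dt = -s.beta_x / np.sqrt(sig2) - t * theta * s.se_x**2 / sig2
            return float(np.sum(psi * dt))

        grid = np.linspace(est.theta_hat - 0.5, est.theta_hat + 0.5, 20_001)
        vals = np.array([score(t) for t in grid])
        flips = np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)
        roots = [optimize.brentq(score, grid[i], grid[i + 1]) for i in flips]
        assert min(abs(est.theta_hat - r) for r in roots) < 1e-6


class TestLasso:
    def test_huge_lambda_equals_full_ivw(self, rng):
        s = simulate_summary(rng, J=10, theta=0.2)
        est = mr_lasso(s, lambda_path=np.array([1e9]))
        full = ivw(s)
        assert est.theta_hat == pytest.approx(full.theta_hat, rel=1e-10)
        assert est.n_snps_used == 10

    def test_outlier_excluded(self, rng):
        bx = rng.uniform(0.1, 0.3, 10)
        by = 0.2 * bx + rng.normal(0, 0.002, 10)
        by[0] = 0.2 * bx[0] + 0.2
        s = make_summary(bx, by, se_y=[0.01] * 10)
        est = mr_lasso(s)
        assert not est.extras["retained_mask"][0]
        pruned = make_summary(bx[1:], by[1:], se_y=[0.01] * 9)
        assert est.theta_hat == pytest.approx(ivw(pruned).theta_hat, abs=0.02)

    def test_coordinate_descent_matches_fixed_point_oracle(self, rng):
        """Independent soft-threshold fixed-point iteration at fixed lambda."""
        from mrselect.estimators import _lasso_fit

        s = simulate_summary(rng, J=8, theta=0.1)
        bx, by = s.beta_x, s.beta_y
        w = 1.0 / s.se_y**2
        lam = 0.5 * np.max(w * np.abs(by - ivw(s).theta_hat * bx))
        theta, gamma = _lasso_fit(bx, by, w, lam, 0.0, np.zeros(8))
        # oracle: damped fixed-point iteration from a different start
        th_o, g_o = 1.0, np.ones(8)
        for _ in range(200_000):
            th_new = float(np.sum(w * bx * (by - g_o)) / np.sum(w * bx**2))
            resid = by - th_new * bx
            g_new = np.sign(resid) * np.maximum(np.abs(resid) - lam / w, 0.0)
            if abs(th_new - th_o) < 1e-14 and np.max(np.abs(g_new - g_o)) < 1e-14:
                break
            th_o, g_o = th_new, g_new
        assert theta == pytest.approx(th_o, abs=1e-8)
        np.testing.assert_allclose(gamma, g_o, atol=1e-8)

    def test_degenerate_when_too_few_retained(self):
        with pytest.raises(InsufficientInstrumentsError):
            mr_lasso(make_summary([0.1, 0.2], [0.01, 0.04]))


# ---------------------------------------------------------------------------
# shared invariants


ALL_METHODS = list(E.METHODS)


class TestSharedInvariants:
    def test_consensus_under_homogeneity(self):
        """All ratio estimates identical => every method returns that value
        (MBE within grid resolution)."""
        bx = np.array([0.1, 0.15, 0.2, 0.25, 0.3])
        s = make_summary(bx, 0.4 * bx, se_y=[0.05] * 5)
        results = estimate_all(s, seed=11, n_boot=100)
        for name, est in results.items():
            assert not isinstance(est, Exception), f"{name} raised {est}"
            tol = 0.02 if name in ("mbe", "conmix") else 1e-6
            assert est.theta_hat == pytest.approx(0.4, abs=tol), name

    def test_scale_equivariance(self, rng):
        """Multiplying beta_y and se_y by k multiplies every estimate by k."""
        s = simulate_summary(rng, J=12, theta=0.2)
        k = 2.5
        scaled = make_summary(s.beta_x, k * s.beta_y, s.se_x, k * s.se_y)
        base = estimate_all(s, seed=13, n_boot=100)
        scl = estimate_all(scaled, seed=13, n_boot=100)
        for name in ALL_METHODS:
            assert scl[name].theta_hat == pytest.approx(
                k * base[name].theta_hat, rel=1e-6, abs=1e-4
            ), name
            assert scl[name].se == pytest.approx(k * base[name].se, rel=0.05), name

    def test_sign_equivariance_single_snp_flip(self, rng):
        """Flipping the signs of one SNP's beta_x and beta_y changes no
        point estimate."""
        s = simulate_summary(rng, J=12, theta=0.2)
        bx, by = s.beta_x.copy(), s.beta_y.copy()
        bx[4] *= -1
        by[4] *= -1
        flipped = make_summary(bx, by, s.se_x, s.se_y)
        base = estimate_all(s, seed=17, n_boot=100)
        flip = estimate_all(flipped, seed=17, n_boot=100)
        for name in ALL_METHODS:
            assert flip[name].theta_hat == pytest.approx(
                base[name].theta_hat, rel=1e-8, abs=1e-10
            ), name

    def test_null_calibration_summary_level(self):
        """On no-selection null data, rejection at 0.05 stays within the
        exact binomial band over 500 replicates (MR-Egger, weighted median
        and MBE may be conservative)."""
        rng = np.random.default_rng(2024)
        reps = 500
        rej = {name: 0 for name in ALL_METHODS}
        for r in range(reps):
            s = simulate_summary(rng, J=50, theta=0.0)
            results = estimate_all(s, seed=3_000 + r, n_boot=200)
            for name, est in results.items():
                assert not isinstance(est, Exception), f"{name} raised {est}"
                rej[name] += est.p_value < 0.05
        lo, hi = stats.binom.interval(0.95, reps, 0.05)
        conservative_ok = {"egger", "weighted_median", "mbe"}
        for name, count in rej.items():
            assert count <= hi, f"{name}: {count}/{reps} rejections (inflated)"
            if name not in conservative_ok:
                assert count >= lo, f"{name}: {count}/{reps} rejections (too few)"
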