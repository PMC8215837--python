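"""Univariable estimators: worked values, oracles, calibration properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cardiomr as c
from cardiomr.estimators import (
    RatioEstimates,
    _median_interp,
    _silverman_bandwidth,
    egger,
    ivw,
    mode_based,
    penalized_weights,
    wald_ratios,
    weighted_median,
)
from cardiomr.sumstats import AnalysisError, HarmonizedSet, InputError

from .conftest import make_harmonized


def hset(bx, sx, by, sy):
    bx, sx, by, sy = map(np.atleast_1d, (bx, sx, by, sy))
    ids = [f"rs{i}" for i in range(bx.size)]
    return HarmonizedSet(["X"], "Y", ids, bx[:, None].astype(float),
                         sx[:, None].astype(float), by.astype(float), sy.astype(float))


class TestWaldRatios:
    def test_first_order_worked_value(self):
        r = wald_ratios(hset(0.2, 0.02, 0.1, 0.05))
        assert r.theta[0] == pytest.approx(0.5)
        assert r.sigma[0] == pytest.approx(0.25)

    def test_null_numerator(self):
        r = wald_ratios(hset(0.2, 0.02, 0.0, 0.05))
        assert r.theta[0] == 0.0 and r.sigma[0] == pytest.approx(0.25)

    def test_second_order_matches_delta_method_oracle(self):
        bx, sx, by, sy = 0.2, 0.02, 0.1, 0.05
        r = wald_ratios(hset(bx, sx, by, sy), se_order="second")
        # numeric delta method: finite-difference gradient of by/bx
        eps = 1e-7
        dfdy = ((by + eps) / bx - by / bx) / eps
        dfdx = (by / (bx + eps) - by / bx) / eps
        oracle = np.sqrt(dfdy**2 * sy**2 + dfdx**2 * sx**2)
        assert r.sigma[0] == pytest.approx(oracle, rel=1e-5)

    def test_zero_exposure_beta_names_variant(self):
        with pytest.raises(InputError, match="rs0"):
            wald_ratios(hset([0.0, 0.2], [0.02, 0.02], [0.1, 0.1], [0.05, 0.05]))


class TestIVW:
    def test_single_variant_reduces_to_wald_ratio(self):
        est = ivw(RatioEstimates(["a"], [0.5], [0.25]))
        assert (est.theta, est.se) == (0.5, 0.25)

    def test_equal_weight_closed_form(self):
        est = ivw(RatioEstimates(["a", "b"], [0.5, 0.3], [0.25, 0.25]))
        assert est.theta == pytest.approx(0.4)
        assert est.se == pytest.approx(0.25 / np.sqrt(2))

    def test_zero_heterogeneity_random_equals_fixed(self):
        r = RatioEstimates(list("abc"), [0.2, 0.2, 0.2], [0.1, 0.2, 0.3])
        fe, re = ivw(r, "fixed"), ivw(r, "multiplicative_random")
        assert fe.heterogeneity_Q == pytest.approx(0.0, abs=1e-12)
        assert re.se == pytest.approx(fe.se)

    def test_random_effects_inflates_under_heterogeneity(self):
        r = RatioEstimates(list("abcd"), [0.0, 0.2, 0.6, 1.0], [0.02] * 4)
        assert ivw(r, "multiplicative_random").se > ivw(r, "fixed").se

    @pytest.mark.parametrize("seed", range(10))
    def test_weight_formula_equals_origin_weighted_regression(self, seed):
        rng = np.random.default_rng(seed)
        J = int(rng.integers(3, 40))
        bx = rng.normal(0.1, 0.05, J)
        bx[np.abs(bx) < 0.01] = 0.05
        sy = rng.uniform(0.005, 0.05, J)
        by = 0.3 * bx + rng.normal(0, sy)
        h = hset(bx, np.full(J, 0.01), by, sy)
        est = ivw(wald_ratios(h))
        # independent path: origin-constrained WLS of beta_Y on beta_X, weights se_Y^-2
        w = sy**-2.0
        slope = np.sum(w * bx * by) / np.sum(w * bx * bx)
        se = np.sqrt(1.0 / np.sum(w * bx * bx))
        assert est.theta == pytest.approx(slope, abs=1e-10)
        assert est.se == pytest.approx(se, abs=1e-10)

    def test_empty_input_rejected(self):
        with pytest.raises(AnalysisError):
            ivw(RatioEstimates([], [], []))


class TestEgger:
    def test_exact_linear_data_recovered_to_machine_precision(self):
        bx = np.array([0.1, 0.2, 0.3])
        by = 0.02 + 0.5 * bx
        est = egger(hset(bx, [0.01] * 3, by, [0.03, 0.02, 0.05]))
        assert est.theta == pytest.approx(0.5, abs=1e-10)
        assert est.intercept == pytest.approx(0.02, abs=1e-10)
        assert est.heterogeneity_Q == pytest.approx(0.0, abs=1e-12)

    def test_orientation_invariance(self):
        bx = np.array([0.1, -0.2, 0.3, 0.15])
        by = 0.01 + 0.4 * bx
        by[1] = 0.01 - 0.4 * 0.2  # consistent with flipped orientation
        h1 = hset(bx, [0.01] * 4, by, [0.02] * 4)
        bx2, by2 = bx.copy(), by.copy()
        bx2[1] *= -1
        by2[1] *= -1
        h2 = hset(bx2, [0.01] * 4, by2, [0.02] * 4)
        e1, e2 = egger(h1), egger(h2)
        assert e1.theta == pytest.approx(e2.theta, abs=1e-12)
        assert e1.intercept == pytest.approx(e2.intercept, abs=1e-12)

    def test_too_few_variants(self):
        with pytest.raises(AnalysisError):
            egger(hset([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.02] * 2))

    def test_zero_spread_is_singular(self):
        with pytest.raises(AnalysisError):
            egger(hset([0.1] * 4, [0.01] * 4, [0.05] * 4, [0.02] * 4))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_directional_pleiotropy_recovered_under_inside(self, seed):
        """With pleiotropic effects independent of instrument strength, the
        slope CI covers the causal effect and the intercept CI the mean
        pleiotropic effect."""
        rng = np.random.default_rng(seed)
        J, theta, alpha0 = 50, 0.2, 0.03
        sx = np.full(J, 0.004)
        sy = np.full(J, 0.004)
        bx_true = rng.uniform(5.5, 30, J) * sx
        by_true = theta * bx_true + rng.normal(alpha0, 0.01, J)
        h = hset(bx_true + rng.normal(0, sx), sx, by_true + rng.normal(0, sy), sy)
        est = egger(h)
        assert est.ci_low <= theta <= est.ci_high
        lo = est.intercept - 1.96 * est.intercept_se
        hi = est.intercept + 1.96 * est.intercept_se
        assert lo <= alpha0 <= hi


def median_scan_oracle(theta, weights, n_grid=2_000_001):
    """Brute-force scan: smallest grid value whose interpolated percentile >= 50."""
    order = np.argsort(theta)
    t, w = np.asarray(theta, float)[order], np.asarray(weights, float)[order]
    S = np.cumsum(w)
    p = 100 * (S - w / 2) / S[-1]
    grid = np.linspace(t[0], t[-1], n_grid)
    pc = np.interp(grid, t, p)
    return float(grid[np.searchsorted(pc, 50.0)])


class TestWeightedMedian:
    def test_equal_weights_give_middle_value(self):
        r = RatioEstimates(list("abc"), [0.2, 0.5, 0.9], [1.0, 1.0, 1.0])
        assert weighted_median(r, n_boot=100, seed=1).theta == pytest.approx(0.5)

    def test_worked_interpolation_value_and_scan_oracle(self):
        sigma = 1.0 / np.sqrt([1.0, 1.0, 8.0])
        r = RatioEstimates(list("abc"), [0.2, 0.5, 0.9], sigma)
        est = weighted_median(r, n_boot=100, seed=1)
        assert est.theta == pytest.approx(0.5 + 0.4 * (50 - 15) / (60 - 15), abs=1e-9)
        assert est.theta == pytest.approx(
            median_scan_oracle([0.2, 0.5, 0.9], [1, 1, 8]), abs=1e-5
        )

    def test_degenerate_distribution_stable_across_seeds(self):
        r = RatioEstimates(list("abcd"), [0.4] * 4, [0.01] * 4)
        e1 = weighted_median(r, n_boot=500, seed=1)
        e2 = weighted_median(r, n_boot=500, seed=2)
        assert e1.theta == 0.4
        assert e1.se < 0.02 and abs(e1.se - e2.se) < 0.005

    def test_tolerates_forty_percent_invalid_instruments(self):
        """Offset 40% of ratios by +1: the median stays near truth, IVW does not."""
        rng = np.random.default_rng(77)
        J, theta = 50, 0.2
        sigma = rng.uniform(0.02, 0.05, J)
        t = rng.normal(theta, sigma)
        bad = rng.choice(J, size=20, replace=False)
        t[bad] += 1.0
        sigma[bad] *= 2.0  # invalid instruments are noisier: valid set keeps the weight majority
        r = RatioEstimates([f"v{i}" for i in range(J)], t, sigma)
        med = weighted_median(r, n_boot=200, seed=3)
        fe = ivw(r)
        assert abs(med.theta - theta) <= 3 * med.se
        assert abs(fe.theta - theta) > 3 * fe.se


class TestModeBased:
    def test_point_mass_returns_common_value(self):
        r = RatioEstimates(list("abc"), [0.4] * 3, [0.05] * 3)
        assert mode_based(r, n_boot=100, seed=1).theta == pytest.approx(0.4)

    def test_resists_outliers_where_mean_does_not(self):
        rng = np.random.default_rng(11)
        t = np.concatenate([rng.normal(0.2, 0.02, 28), [1.5, 1.5]])
        sigma = np.full(30, 0.05)
        r = RatioEstimates([f"v{i}" for i in range(30)], t, sigma)
        est = mode_based(r, n_boot=100, seed=2)
        assert abs(est.theta - 0.2) < 0.05
        assert abs(t.mean() - 0.2) > 0.05

    def test_mode_matches_dense_grid_brute_force(self):
        rng = np.random.default_rng(4)
        t = rng.normal(0.3, 0.1, 25)
        sigma = rng.uniform(0.02, 0.2, 25)
        r = RatioEstimates([f"v{i}" for i in range(25)], t, sigma)
        est = mode_based(r, n_boot=10, seed=1)
        # brute force: same weighted KDE evaluated on a 50x denser grid
        w = r.weights / r.weights.sum()
        hband = _silverman_bandwidth(t, 1.0)
        grid = np.linspace(t.min() - 3 * sigma.max(), t.max() + 3 * sigma.max(), 25_600)
        dens = np.exp(-0.5 * ((grid[:, None] - t) / hband) ** 2) @ w
        assert est.theta == pytest.approx(grid[np.argmax(dens)], abs=2e-3)

    def test_doubling_phi_never_increases_local_maxima(self):
        rng = np.random.default_rng(8)
        t = np.concatenate([rng.normal(0.0, 0.05, 15), rng.normal(1.0, 0.05, 15)])
        sigma = np.full(30, 0.05)
        w = sigma**-2.0
        grid = np.linspace(-0.5, 1.5, 2048)

        def n_maxima(phi):
            h = _silverman_bandwidth(t, phi)
            d = np.exp(-0.5 * ((grid[:, None] - t) / h) ** 2) @ (w / w.sum())
            return int(np.sum((d[1:-1] > d[:-2]) & (d[1:-1] > d[2:])))

        for phi in (0.25, 0.5, 1.0, 2.0):
            assert n_maxima(2 * phi) <= n_maxima(phi)


class TestPenalizedWeights:
    def test_concordant_variants_unchanged(self):
        r = RatioEstimates(list("abc"), [0.3, 0.31, 0.29], [0.1, 0.1, 0.1])
        p = penalized_weights(r, 0.3)
        np.testing.assert_allclose(p.weights, r.weights)

    def test_outlier_weight_scaled_by_twenty_q(self):
        from scipy import stats

        r = RatioEstimates(["a"], [1.0], [0.1])
        q = stats.chi2.sf(r.weights[0] * (1.0 - 0.3) ** 2, df=1)
        p = penalized_weights(r, 0.3)
        assert p.weights[0] == pytest.approx(r.weights[0] * 20 * q)

    def test_penalization_moves_ivw_toward_valid_variants(self):
        rng = np.random.default_rng(21)
        J, theta = 30, 0.3
        sigma = rng.uniform(0.01, 0.03, J)
        t = rng.normal(theta, sigma)
        t[0] = 2.0  # planted outlier with a precise (high-weight) ratio
        sigma[0] = 0.01
        r = RatioEstimates([f"v{i}" for i in range(J)], t, sigma)
        plain = ivw(r)
        pen = ivw(penalized_weights(r, plain.theta))
        assert abs(pen.theta - theta) < abs(plain.theta - theta)


@settings(max_examples=25, deadline=None)
@given(
    scale=st.floats(0.1, 10, allow_nan=False),
    seed=st.integers(0, 1000),
)
def test_estimators_equivariant_in_outcome_units(scale, seed):
    """Multiplying every beta_Y and se_Y by c multiplies estimates and SEs by c."""
    h = make_harmonized(0.3, 20, seed=seed)
    h2 = HarmonizedSet(
        h.exposure_names, h.outcome_name, h.variant_ids,
        h.beta_exp, h.se_exp, h.beta_out * scale, h.se_out * scale,
    )
    for fn in (lambda hh: ivw(wald_ratios(hh)), egger):
        e1, e2 = fn(h), fn(h2)
        assert e2.theta == pytest.approx(scale * e1.theta, rel=1e-9)
        assert e2.se == pytest.approx(scale * e1.se, rel=1e-9)
    m1 = weighted_median(wald_ratios(h), n_boot=50, seed=5)
    m2 = weighted_median(wald_ratios(h2), n_boot=50, seed=5)
    assert m2.theta == pytest.approx(scale * m1.theta, rel=1e-9)
    assert m2.se == pytest.approx(scale * m1.se, rel=1e-6)
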