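"""Causal-effect estimators against independent oracles and their invariants.

Oracles are deliberately implemented by a different route than the package:
weighted least squares via lstsq on sqrt-weight-scaled designs, the weighted
median via an explicit cumulative-weight walk, the mode via a brute-force
density evaluation, and the Wald-ratio SE via Monte-Carlo draws.
"""

import math

import numpy as np
import pytest
from scipy import stats

from conftest import make_instruments
from mrkit.estimators import (
    InsufficientInstrumentsError,
    UndefinedRatioError,
    egger,
    ivw_mre,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from mrkit.instruments import HarmonisedInstrument


def wls_origin_oracle(bx, by, sy):
    """Weighted least squares through the origin via scaled lstsq."""
    w = np.asarray(sy, float) ** -2.0
    A = (np.sqrt(w) * np.asarray(bx, float))[:, None]
    b = np.sqrt(w) * np.asarray(by, float)
    theta, *_ = np.linalg.lstsq(A, b, rcond=None)
    return float(theta[0])


def wls_intercept_oracle(bx, by, sy):
    """Weighted least squares with intercept via scaled lstsq."""
    bx, by = np.asarray(bx, float), np.asarray(by, float)
    flip = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * flip, by * flip
    w = np.asarray(sy, float) ** -2.0
    A = np.sqrt(w)[:, None] * np.column_stack([np.ones_like(bx), bx])
    coef, *_ = np.linalg.lstsq(A, np.sqrt(w) * by, rcond=None)
    return float(coef[0]), float(coef[1])  # intercept, slope


def weighted_median_oracle(ratios, weights):
    """Cumulative-weight walk with linear interpolation at 0.5."""
    pairs = sorted(zip(ratios, weights))
    total = sum(w for _, w in pairs)
    s = 0.0
    pts = []
    for t, w in pairs:
        s += w
        pts.append((s / total - w / total / 2.0, t))
    for (p0, t0), (p1, t1) in zip(pts, pts[1:]):
        if p0 <= 0.5 <= p1:
            return t0 + (t1 - t0) * (0.5 - p0) / (p1 - p0)
    return pts[0][1] if 0.5 < pts[0][0] else pts[-1][1]


class TestWaldRatio:
    def test_null_numerator(self):
        (inst,) = make_instruments([1.0], [0.0], [0.1])
        est = wald_ratio(inst)
        assert est.theta == 0.0 and est.se == 0.1

    def test_unit_denominator(self):
        (inst,) = make_instruments([1.0], [0.5], [0.1])
        est = wald_ratio(inst)
        assert est.theta == 0.5 and est.se == 0.1
        assert est.ci_low == pytest.approx(0.5 - 1.959964 * 0.1, abs=1e-6)
        assert est.pval == pytest.approx(2 * stats.norm.sf(5.0), rel=1e-12)

    def test_second_order_se_matches_monte_carlo(self):
        inst = HarmonisedInstrument.from_effects("rs1", 0.5, 0.05, 0.25, 0.1)
        first = wald_ratio(inst)
        assert first.theta == pytest.approx(0.5, abs=1e-12)
        assert first.se == pytest.approx(0.2, abs=1e-12)
        second = wald_ratio(inst, second_order=True)
        rng = np.random.default_rng(202)
        bx = rng.normal(0.5, 0.05, size=1_000_000)
        by = rng.normal(0.25, 0.1, size=1_000_000)
        mc_sd = np.std(by / bx, ddof=1)
        # the ratio is mildly non-linear in beta_x, so allow a few percent
        assert second.se == pytest.approx(mc_sd, rel=0.03)
        assert second.se > first.se

    def test_zero_exposure_effect_raises(self):
        inst = HarmonisedInstrument.from_effects("rs1", 1.0, 0.01, 0.5, 0.1)
        object.__setattr__(inst, "beta_x", 0.0)
        with pytest.raises(UndefinedRatioError):
            wald_ratio(inst)


class TestIvwMre:
    def test_homogeneous_instruments(self):
        inst = make_instruments([1.0] * 3, [0.5] * 3, [0.1] * 3)
        est = ivw_mre(inst)
        assert est.theta == pytest.approx(0.5, abs=1e-12)
        # Q = 0 so the multiplicative scale floors at 1: fixed-effect SE
        assert est.se == pytest.approx(math.sqrt(1.0 / 300.0), abs=1e-12)

    def test_heterogeneous_derived_example(self):
        inst = make_instruments([1.0] * 3, [0.4, 0.5, 0.6], [0.1] * 3)
        est = ivw_mre(inst)
        assert est.theta == pytest.approx(0.5, abs=1e-12)
        # Q = (0.1^2 + 0 + 0.1^2)/0.01 = 2.0 -> phi = max(1, sqrt(1)) = 1
        assert est.se == pytest.approx(math.sqrt(1.0 / 300.0), abs=1e-12)
        assert est.theta == pytest.approx(
            wls_origin_oracle([1, 1, 1], [0.4, 0.5, 0.6], [0.1] * 3), abs=1e-12
        )

    def test_overdispersion_inflates_se(self):
        inst = make_instruments([1.0] * 3, [0.1, 0.5, 0.9], [0.1] * 3)
        est = ivw_mre(inst)
        # Q = 32 -> phi = sqrt(16) = 4
        assert est.se == pytest.approx(4.0 * math.sqrt(1.0 / 300.0), abs=1e-12)

    def test_single_instrument_raises(self):
        with pytest.raises(InsufficientInstrumentsError, match="wald_ratio"):
            ivw_mre(make_instruments([1.0], [0.5], [0.1]))

    def test_duplicated_instrument_equals_wald(self):
        (single,) = make_instruments([0.8], [0.24], [0.05])
        wald = wald_ratio(single)
        dup = ivw_mre([single] * 5)
        assert dup.theta == pytest.approx(wald.theta, abs=1e-12)

    def test_orientation_invariance(self):
        bx, by, sy = [0.5, -0.3, 0.8], [0.1, -0.05, 0.2], [0.1, 0.08, 0.12]
        base = ivw_mre(make_instruments(bx, by, sy))
        bx2, by2 = list(bx), list(by)
        bx2[1], by2[1] = -bx2[1], -by2[1]
        flipped = ivw_mre(make_instruments(bx2, by2, sy))
        assert flipped.theta == pytest.approx(base.theta, abs=1e-12)
        assert flipped.se == pytest.approx(base.se, abs=1e-12)

    def test_random_sets_match_wls_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            J = rng.integers(3, 12)
            bx = rng.normal(0.2, 0.1, J)
            bx[bx == 0] = 0.05
            by = rng.normal(0.02, 0.05, J)
            sy = rng.uniform(0.02, 0.2, J)
            est = ivw_mre(make_instruments(bx, by, sy))
            assert est.theta == pytest.approx(wls_origin_oracle(bx, by, sy), abs=1e-8)


class TestEgger:
    def test_collinear_derived_example(self):
        inst = make_instruments([1.0, 2.0, 3.0], [0.6, 1.1, 1.6], [0.1] * 3)
        est = egger(inst)
        assert est.slope.theta == pytest.approx(0.5, abs=1e-9)
        assert est.intercept == pytest.approx(0.1, abs=1e-9)

    def test_no_pleiotropy_identity(self):
        inst = make_instruments([0.5, 1.0, 1.5, 2.0], [0.25, 0.5, 0.75, 1.0], [0.1] * 4)
        est = egger(inst)
        assert est.slope.theta == pytest.approx(0.5, abs=1e-9)
        assert est.intercept == pytest.approx(0.0, abs=1e-9)

    def test_two_instruments_raises(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(make_instruments([1.0, 2.0], [0.5, 1.0], [0.1] * 2))

    def test_matches_wls_oracle_on_random_sets(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            J = rng.integers(4, 15)
            bx = rng.normal(0.3, 0.2, J)
            bx[bx == 0] = 0.05
            by = rng.normal(0.05, 0.1, J)
            sy = rng.uniform(0.02, 0.2, J)
            est = egger(make_instruments(bx, by, sy))
            intercept, slope = wls_intercept_oracle(bx, by, sy)
            assert est.slope.theta == pytest.approx(slope, abs=1e-8)
            assert est.intercept == pytest.approx(intercept, abs=1e-8)

    def test_reorientation_makes_sign_flips_harmless(self):
        bx, by, sy = [0.5, 0.3, 0.8, 0.2], [0.12, 0.08, 0.21, 0.04], [0.1] * 4
        base = egger(make_instruments(bx, by, sy))
        bx2 = [-bx[0]] + bx[1:]
        by2 = [-by[0]] + by[1:]
        flipped = egger(make_instruments(bx2, by2, sy))
        assert flipped.slope.theta == pytest.approx(base.slope.theta, abs=1e-12)
        assert flipped.intercept == pytest.approx(base.intercept, abs=1e-12)

    def test_t_inference_degrees_of_freedom(self):
        inst = make_instruments([0.5, 0.9, 1.4, 2.0, 0.7], [0.3, 0.4, 0.8, 0.9, 0.35], [0.1] * 5)
        est = egger(inst)
        tstat = est.slope.theta / est.slope.se
        assert est.slope.pval == pytest.approx(2 * stats.t.sf(abs(tstat), 3), rel=1e-9)


class TestWeightedMedian:
    def test_interpolated_derived_example(self):
        # ratios {1,2,3} with weights {1,1,2}: interpolate between cumulative
        # midpoints 0.375 and 0.75 -> 2 + (0.5-0.375)/0.375 = 7/3
        inst = make_instruments([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [1.0, 1.0, 1.0 / math.sqrt(2)])
        est = weighted_median(inst, n_boot=100, seed=1)
        assert est.theta == pytest.approx(7.0 / 3.0, abs=1e-12)
        w = np.array([1.0, 1.0, 2.0])
        assert est.theta == pytest.approx(weighted_median_oracle([1.0, 2.0, 3.0], w), abs=1e-12)

    def test_degenerate_ratios(self):
        inst = make_instruments([1.0, 2.0, 0.5], [0.5, 1.0, 0.25], [0.1, 0.3, 0.2])
        est = weighted_median(inst, n_boot=100, seed=1)
        assert est.theta == pytest.approx(0.5, abs=1e-12)

    def test_resists_minority_outlier(self):
        inst = make_instruments([1.0] * 4, [0.5, 0.5, 0.5, 50.0], [0.1, 0.1, 0.1, 0.12])
        est = weighted_median(inst, n_boot=100, seed=1)
        assert est.theta < 1.0

    def test_matches_walk_oracle_on_random_sets(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            J = rng.integers(3, 10)
            bx = rng.uniform(0.2, 1.0, J)
            by = rng.normal(0.1, 0.2, J)
            sy = rng.uniform(0.05, 0.3, J)
            est = weighted_median(make_instruments(bx, by, sy), n_boot=100, seed=5)
            ratios = by / bx
            weights = (sy / np.abs(bx)) ** -2.0
            assert est.theta == pytest.approx(weighted_median_oracle(ratios, weights), abs=1e-8)

    def test_bootstrap_reproducible_and_seed_sensitive(self):
        inst = make_instruments([1.0, 0.8, 1.2], [0.5, 0.4, 0.66], [0.1, 0.1, 0.1])
        a = weighted_median(inst, n_boot=200, seed=9)
        b = weighted_median(inst, n_boot=200, seed=9)
        c = weighted_median(inst, n_boot=200, seed=10)
        assert a.se == b.se
        assert a.se != c.se

    def test_too_few_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(make_instruments([1.0, 1.0], [0.5, 0.6], [0.1, 0.1]), 100, 1)


class TestWeightedMode:
    def test_point_mass(self):
        inst = make_instruments([1.0, 2.0, 0.5], [0.5, 1.0, 0.25], [0.1, 0.3, 0.2])
        est = weighted_mode(inst, n_boot=100, seed=1)
        assert est.theta == pytest.approx(0.5, abs=1e-12)

    def test_cluster_beats_outlier(self):
        inst = make_instruments([1.0] * 4, [0.50, 0.51, 0.49, 3.0], [0.1] * 4)
        est = weighted_mode(inst, n_boot=100, seed=1)
        assert 0.47 <= est.theta <= 0.53
        # independent dense-grid check at 1e-4 resolution
        ratios = np.array([0.50, 0.51, 0.49, 3.0])
        w = np.full(4, 0.25)
        med = weighted_median_oracle_local(ratios, w)
        mad = weighted_median_oracle_local(np.abs(ratios - med), w) * 1.4826
        sd = math.sqrt(np.sum(w * (ratios - np.sum(w * ratios)) ** 2))
        h = 0.9 * min(sd, mad) * 4 ** (-0.2)
        grid = np.arange(ratios.min(), ratios.max() + 1e-4, 1e-4)
        dens = np.zeros_like(grid)
        for r, wi in zip(ratios, w):
            dens += wi * np.exp(-0.5 * ((grid - r) / h) ** 2)
        oracle = grid[np.argmax(dens)]
        assert est.theta == pytest.approx(oracle, abs=5e-3)

    def test_phi_keeps_estimate_in_data_range(self):
        inst = make_instruments([1.0] * 5, [0.2, 0.3, 0.5, 0.8, 1.3], [0.1] * 5)
        lo, hi = 0.2, 1.3
        for phi in (0.5, 1.0, 2.0, 4.0):
            est = weighted_mode(inst, phi=phi, n_boot=100, seed=2)
            assert lo <= est.theta <= hi

    def test_too_few_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_mode(make_instruments([1.0, 1.0], [0.5, 0.6], [0.1, 0.1]), 1.0, 100, 1)


def weighted_median_oracle_local(ratios, weights):
    return weighted_median_oracle(list(ratios), list(weights))


class TestEstimateContract:
    def test_or_fields_and_ci_bracket(self):
        inst = make_instruments([1.0] * 3, [0.4, 0.5, 0.6], [0.1] * 3)
        for est in (ivw_mre(inst), weighted_median(inst, 100, 3), weighted_mode(inst, 1.0, 100, 3)):
            assert est.or_point == pytest.approx(math.exp(est.theta), rel=1e-12)
            assert est.ci_low < est.theta < est.ci_high
            assert 0 < est.pval <= 1
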