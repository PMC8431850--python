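"""Colocalization statistics and the Costes threshold search strategies."""

import math

import numpy as np
import pytest

from microquant import (
    FixtureSpec,
    IntensityImage,
    UndefinedCorrelationError,
    below_threshold_corr,
    coloc_stats,
    costes_regression,
    costes_threshold_accurate,
    costes_threshold_canonical,
    costes_threshold_fast,
    costes_threshold_faster,
    make_correlated_pair,
    manders_coefficients,
    pearson_r,
)

from conftest import quantized_image


class TestPearson:
    def test_identical_channels(self, rng):
        a = IntensityImage(rng.random((8, 8)))
        assert pearson_r(a, a) == pytest.approx(1.0)

    def test_complement_channels(self, rng):
        v = rng.random((8, 8))
        assert pearson_r(IntensityImage(v), IntensityImage(1 - v)) == pytest.approx(-1.0)

    def test_four_pixel_zero_correlation(self):
        a = IntensityImage(np.array([[0.0, 0.0], [1.0, 1.0]]))
        b = IntensityImage(np.array([[0.0, 1.0], [0.0, 1.0]]))
        assert pearson_r(a, b) == pytest.approx(0.0, abs=1e-15)

    def test_constant_channel_raises(self, rng):
        a = IntensityImage(np.full((4, 4), 0.5))
        b = IntensityImage(rng.random((4, 4)))
        with pytest.raises(UndefinedCorrelationError):
            pearson_r(a, b)

    def test_mask_restricts_pixels(self, rng):
        a = IntensityImage(rng.random((6, 6)))
        b = IntensityImage(rng.random((6, 6)))
        mask = np.zeros((6, 6), bool)
        mask[:3] = True
        expected = np.corrcoef(a.values[mask], b.values[mask])[0, 1]
        assert pearson_r(a, b, mask) == pytest.approx(expected, abs=1e-12)


class TestRegression:
    def test_exact_linear_relation(self, rng):
        v = rng.random((10, 10)) * 0.4
        a = IntensityImage(v)
        b = IntensityImage(2 * v + 0.1)
        slope, intercept = costes_regression(a, b)
        assert slope == pytest.approx(2.0, abs=1e-9)
        assert intercept == pytest.approx(0.1, abs=1e-9)

    def test_identity_relation(self, rng):
        v = rng.random((10, 10))
        slope, intercept = costes_regression(IntensityImage(v), IntensityImage(v))
        assert slope == pytest.approx(1.0, abs=1e-12)
        assert intercept == pytest.approx(0.0, abs=1e-12)

    def test_matches_covariance_eigenvector_oracle(self, rng):
        x = rng.random(4096)
        y = (0.6 * x + 0.1 + 0.05 * rng.normal(size=4096)).clip(0, 1)
        a, b = IntensityImage(x.reshape(64, 64)), IntensityImage(y.reshape(64, 64))
        slope, intercept = costes_regression(a, b)
        # oracle: principal eigenvector of the 2x2 covariance matrix
        cov = np.cov(np.stack([x, y]))
        w, v = np.linalg.eigh(cov)
        principal = v[:, np.argmax(w)]
        slope_o = principal[1] / principal[0]
        assert slope == pytest.approx(slope_o, abs=1e-9)
        assert intercept == pytest.approx(y.mean() - slope_o * x.mean(), abs=1e-9)

    def test_constant_a_degenerate(self):
        a = IntensityImage(np.full((4, 4), 0.2))
        b = IntensityImage(np.linspace(0, 1, 16).reshape(4, 4))
        with pytest.raises(Exception):
            costes_regression(a, b)


class TestBelowThresholdCorr:
    def test_full_set_when_nothing_jointly_above(self, rng):
        v = rng.random((8, 8))
        w = rng.random((8, 8))
        a, b = IntensityImage(v), IntensityImage(w)
        slope, intercept = costes_regression(a, b)
        tA = float(v.max())
        r = below_threshold_corr(a, b, tA, slope, intercept)
        assert r == pytest.approx(pearson_r(a, b), abs=1e-12)

    def test_set_is_complement_of_jointly_above(self, rng):
        # when every a-pixel exceeds tA, the population is {b <= tB}
        v = 0.5 + 0.5 * rng.random((6, 6))
        w = rng.random((6, 6))
        a, b = IntensityImage(v), IntensityImage(w)
        slope, intercept = 1.0, 0.3
        tA = 0.2  # below min(a): every pixel has a > tA
        tB = slope * tA + intercept
        sel = w <= tB + 1e-9
        assert 2 <= sel.sum() < sel.size
        expected = np.corrcoef(v[sel], w[sel])[0, 1]
        r = below_threshold_corr(a, b, tA, slope, intercept)
        assert r == pytest.approx(expected, abs=1e-12)

    def test_hand_built_pair_matches_direct_pearson(self):
        v = np.array([[0.1, 0.2, 0.9], [0.4, 0.8, 0.3], [0.7, 0.5, 0.6]])
        w = np.array([[0.2, 0.1, 0.8], [0.5, 0.9, 0.2], [0.6, 0.4, 0.7]])
        a, b = IntensityImage(v), IntensityImage(w)
        slope, intercept = 1.0, 0.0
        tA = 0.55  # excludes pixels with v>0.55 and w>0.55: (0,2),(1,1),(2,0),(2,2)
        keep = ~((v > tA) & (w > tA))
        assert keep.sum() == 5
        expected = np.corrcoef(v[keep], w[keep])[0, 1]
        r = below_threshold_corr(a, b, tA, slope, intercept)
        assert r == pytest.approx(expected, abs=1e-12)

    def test_undefined_on_tiny_set(self):
        a = IntensityImage(np.array([[0.9, 0.8], [0.7, 0.6]]))
        b = IntensityImage(np.array([[0.9, 0.8], [0.7, 0.6]]))
        # tA below everything with slope 1, intercept 0: only <2 pixels retained
        assert below_threshold_corr(a, b, 0.1, 1.0, 0.0) is None


def canonical_oracle(a, b, step):
    """Independent re-implementation of the fixed-step scan using
    np.corrcoef on explicit masks."""
    x, y = a.values.ravel(), b.values.ravel()
    slope, intercept = costes_regression(a, b)
    top = x.max()
    n_cand = int(np.floor(top / step + 1e-9)) + 1
    evals = 0
    for j in range(n_cand):
        tA = top - j * step
        sel = ~((x > tA + 1e-9) & (y > slope * tA + intercept + 1e-9))
        xs, ys = x[sel], y[sel]
        if xs.size < 2 or np.ptp(xs) == 0 or np.ptp(ys) == 0:
            continue
        r = np.corrcoef(xs, ys)[0, 1]
        evals += 1
        if r <= 0:
            return tA, evals, True
    return top - (n_cand - 1) * step, evals, False


class TestCostesCanonical:
    @pytest.mark.parametrize("kind", ["correlated", "independent_uniform"])
    def test_matches_bruteforce_scan_and_evaluation_count(self, kind):
        if kind == "correlated":
            a, b = make_correlated_pair(FixtureSpec(rho=0.5, seed=42, bit_depth=8))
        else:
            rng = np.random.default_rng(42)
            a = IntensityImage(np.round(rng.random((64, 64)) * 255) / 255, 256)
            b = IntensityImage(np.round(rng.random((64, 64)) * 255) / 255, 256)
        res = costes_threshold_canonical(a, b)
        tA_o, evals_o, conv_o = canonical_oracle(a, b, 1.0 / 255.0)
        assert res.tA == pytest.approx(tA_o, abs=1e-12)
        assert res.evaluations == evals_o
        assert res.converged == conv_o

    def test_identical_channels_never_converge(self, rng):
        v = np.round(rng.random((16, 16)) * 255) / 255
        a = IntensityImage(v)
        res = costes_threshold_canonical(a, IntensityImage(v.copy()))
        assert not res.converged

    def test_anticorrelated_pair_single_evaluation(self, rng):
        v = np.round(rng.random((16, 16)) * 255) / 255
        a, b = IntensityImage(v), IntensityImage(1 - v)
        res = costes_threshold_canonical(a, b)
        assert res.converged and res.evaluations == 1
        assert res.tA == pytest.approx(float(v.max()))

    def test_tB_coupled_through_regression(self):
        spec = FixtureSpec(rho=0.7, seed=3, bit_depth=8)
        a, b = make_correlated_pair(spec)
        res = costes_threshold_canonical(a, b)
        assert res.tB == pytest.approx(res.slope * res.tA + res.intercept, abs=1e-12)


class TestCostesAccurate:
    def test_agrees_with_canonical_on_8bit_grid(self):
        for seed in (0, 1, 2):
            a, b = make_correlated_pair(FixtureSpec(rho=0.6, seed=seed, bit_depth=8))
            acc = costes_threshold_accurate(a, b)
            can = costes_threshold_canonical(a, b, step=1.0 / 255.0)
            assert acc.tA == pytest.approx(can.tA, abs=1e-12)

    def test_few_distinct_values_bounds_evaluations(self, rng):
        # 10 distinct grey values and an exactly affine partner channel:
        # the below-threshold pixel count can change at most 10 times, so
        # the pixel-count gate caps the evaluations at 10
        vals = rng.integers(0, 10, size=(32, 32)) * 25
        a = quantized_image(vals / 255.0)
        b = IntensityImage(vals / 255.0 * 0.5 + 0.2, 256)
        res = costes_threshold_accurate(a, b)
        assert res.evaluations <= 10

    def test_16bit_equals_exhaustive_unit_scan(self):
        a, b = make_correlated_pair(FixtureSpec(rho=0.6, seed=9, bit_depth=16))
        acc = costes_threshold_accurate(a, b)
        can = costes_threshold_canonical(a, b, step=1.0 / 65535.0)
        assert acc.tA == pytest.approx(can.tA, abs=1e-12)
        assert acc.evaluations <= can.evaluations


class TestCostesAccelerated:
    @pytest.mark.parametrize("depth", [8, 16])
    @pytest.mark.parametrize("rho", [0.3, 0.6, 0.9])
    def test_fast_and_faster_match_accurate(self, depth, rho):
        for seed in range(3):
            a, b = make_correlated_pair(
                FixtureSpec(rho=rho, seed=seed + 10 * depth, bit_depth=depth)
            )
            acc = costes_threshold_accurate(a, b)
            fast = costes_threshold_fast(a, b)
            faster = costes_threshold_faster(a, b)
            assert fast.tA == acc.tA
            assert faster.tA == acc.tA

    def test_anticorrelated_single_evaluation_all_modes(self, rng):
        v = np.round(rng.random((16, 16)) * 255) / 255
        a, b = IntensityImage(v), IntensityImage(1 - v)
        for fn in (costes_threshold_fast, costes_threshold_faster):
            res = fn(a, b)
            assert res.converged and res.evaluations == 1

    def test_fast_saves_evaluations_on_correlated_pair(self):
        a, b = make_correlated_pair(FixtureSpec(rho=0.8, seed=4, bit_depth=8))
        fast = costes_threshold_fast(a, b)
        acc = costes_threshold_accurate(a, b)
        assert fast.evaluations < acc.evaluations

    def test_faster_cycle_count_bounded_by_geometric_shrink(self):
        for depth in (8, 16):
            a, b = make_correlated_pair(FixtureSpec(rho=0.6, seed=5, bit_depth=depth))
            res = costes_threshold_faster(a, b)
            bound = math.ceil(math.log(a.grey_levels) / math.log(6 / 5)) + 2
            assert res.cycles is not None and res.cycles <= bound


class TestColocStats:
    def test_thresholds_zero_full_manders(self, rng):
        v = (0.1 + 0.9 * rng.random((8, 8)))
        w = (0.1 + 0.9 * rng.random((8, 8)))
        m1, m2 = manders_coefficients(
            IntensityImage(v), IntensityImage(w), 0.0, 0.0
        )
        assert m1 == 1.0 and m2 == 1.0

    def test_disjoint_supports_zero_manders(self):
        v = np.array([[0.8, 0.0], [0.6, 0.0]])
        w = np.array([[0.0, 0.7], [0.0, 0.9]])
        m1, m2 = manders_coefficients(IntensityImage(v), IntensityImage(w), 0.2, 0.2)
        assert m1 == 0.0 and m2 == 0.0

    def test_hand_built_2x2_arithmetic(self):
        a = IntensityImage(np.array([[0.2, 0.8], [0.4, 0.6]]))
        b = IntensityImage(np.array([[0.1, 0.9], [0.7, 0.3]]))
        # tA=0.5, tB=0.5: b>tB at (0,1),(1,0); a>tA at (0,1),(1,1)
        m1, m2 = manders_coefficients(a, b, 0.5, 0.5)
        assert m1 == pytest.approx((0.8 + 0.4) / 2.0)
        assert m2 == pytest.approx((0.9 + 0.3) / 2.0)

    def test_stats_ranges_and_costes_coupling(self):
        a, b = make_correlated_pair(FixtureSpec(rho=0.7, seed=6, bit_depth=8))
        stats = coloc_stats(a, b, costes_mode="faster")
        assert -1 <= stats.pearson <= 1
        for v in (stats.manders_m1, stats.manders_m2, stats.costes_c1, stats.costes_c2):
            assert 0.0 <= v <= 1.0
        assert stats.costes.mode == "faster"
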