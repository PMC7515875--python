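"""Statistical core: Gini, NB test, BH, correlations, robust slope."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from mei.stats import (
    bh_adjust,
    correlation_differential,
    delta_gini,
    exon_intron_correlation,
    gini_unbiased,
    nb_test,
    rescale_by_min,
    robust_slope,
    slope_difference_test,
)


def gini_bruteforce(x):
    x = np.asarray(x, float)
    n = len(x)
    total = sum(abs(a - b) for a in x for b in x)
    return total / (2 * n * (n - 1) * x.mean())


class TestGini:
    @pytest.mark.parametrize(
        "x, expected",
        [
            ([5, 5, 5, 5], 0.0),
            ([0, 1], 1.0),  # 2 / (2*2*1*0.5)
            ([1, 2, 3], 1 / 3),  # 8 / 24
        ],
    )
    def test_known_values(self, x, expected):
        assert gini_unbiased(np.array(x, float)) == pytest.approx(expected, abs=1e-14)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 1e6, allow_nan=False), min_size=2, max_size=40),
        st.floats(1e-3, 1e3),
    )
    def test_matches_oracle_and_scale_invariant(self, xs, c):
        x = np.array(xs)
        if x.mean() == 0:
            return
        g = gini_unbiased(x)
        assert g == pytest.approx(gini_bruteforce(x), abs=1e-9, rel=1e-9)
        assert gini_unbiased(c * x) == pytest.approx(g, abs=1e-10, rel=1e-10)

    def test_zero_mean_is_nan(self):
        assert math.isnan(gini_unbiased(np.zeros(5)))


class TestDeltaGini:
    @pytest.mark.parametrize(
        "gc, gt, rel, ratio",
        [(0.2, 0.4, 1.0, 2.0), (0.3, 0.3, 0.0, 1.0), (0.4, 0.1, -0.75, 0.25)],
    )
    def test_arithmetic(self, gc, gt, rel, ratio):
        got = delta_gini(gc, gt)
        assert got == (pytest.approx(rel), pytest.approx(ratio))

    def test_zero_control_undefined(self):
        rel, ratio = delta_gini(0.0, 0.4)
        assert math.isnan(rel) and math.isnan(ratio)


class TestNBTest:
    def test_identical_groups_null(self):
        x = np.array([50.0] * 12)
        res = nb_test(x, np.array([50.0] * 46))
        assert res.p_value == pytest.approx(1.0)
        assert res.fold_change == pytest.approx(1.0)

    def test_all_zero_gene_p_one(self):
        res = nb_test(np.zeros(5), np.zeros(8))
        assert res.p_value == 1.0

    def test_power_on_fourfold_shift(self, rng):
        r = 1 / 0.05
        sig = 0
        for _ in range(50):
            c = rng.negative_binomial(r, r / (r + 50), 12)
            t = rng.negative_binomial(r, r / (r + 200), 46)
            sig += nb_test(c, t).p_value < 1e-6
        assert sig >= 49

    def test_null_rate_near_nominal(self, rng):
        """Small-scale calibration check (the full grid runs in acceptance)."""
        r = 1 / 0.1
        p = [
            nb_test(
                rng.negative_binomial(r, r / (r + 100), 12),
                rng.negative_binomial(r, r / (r + 100), 46),
            ).p_value
            for _ in range(400)
        ]
        assert 0.0 <= np.mean(np.array(p) < 0.05) <= 0.12

    def test_dispersion_recovered_roughly(self, rng):
        r = 1 / 0.2
        c = rng.negative_binomial(r, r / (r + 300), 200)
        t = rng.negative_binomial(r, r / (r + 300), 200)
        assert nb_test(c, t).dispersion == pytest.approx(0.2, rel=0.5)

    def test_group_too_small(self):
        with pytest.raises(ValueError):
            nb_test(np.array([1.0]), np.array([1.0, 2.0]))


class TestBH:
    def bh_oracle(self, p):
        """Independent step-up implementation."""
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p)
        q = np.empty(m)
        prev = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            prev = min(prev, p[i] * m / rank)
            q[i] = prev
        return q

    def test_hand_computed_example(self):
        assert bh_adjust(np.array([0.01, 0.02, 0.03])) == pytest.approx(
            [0.03, 0.03, 0.03]
        )

    def test_single_and_equal_p(self):
        assert bh_adjust(np.array([0.2])) == pytest.approx([0.2])
        assert bh_adjust(np.array([0.4, 0.4, 0.4])) == pytest.approx([0.4] * 3)

    def test_matches_oracle_on_random_vectors(self, rng):
        for _ in range(25):
            p = rng.uniform(size=rng.integers(1, 60))
            assert bh_adjust(p) == pytest.approx(self.bh_oracle(p), abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))


class TestRescaleByMin:
    def test_positive_min(self):
        assert rescale_by_min(np.array([10.0, 20, 40])) == pytest.approx([1, 2, 4])

    def test_zero_min_with_guard_adds_one(self):
        assert rescale_by_min(np.array([0.0, 3, 9])) == pytest.approx([1, 4, 10])

    def test_zero_min_without_guard_is_nan(self):
        out = rescale_by_min(np.array([0.0, 3.0]), zero_guard=False)
        assert np.isnan(out).all()

    def test_singleton(self):
        assert rescale_by_min(np.array([7.0])) == pytest.approx([1.0])


class TestCorrelation:
    def test_perfect_linear(self):
        x = np.array([1.0, 2, 3, 4, 5])
        assert exon_intron_correlation(x, 2 * x) == pytest.approx(1.0)
        assert exon_intron_correlation(x, -x + 10) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        x = np.array([2.0, 4, 5, 7, 8, 11])
        y = np.array([1.0, 3, 2, 8, 7, 9])
        xc, yc = x - x.mean(), y - y.mean()
        expected = np.sum(xc * yc) / math.sqrt(np.sum(xc**2) * np.sum(yc**2))
        assert exon_intron_correlation(x, y) == pytest.approx(expected, abs=1e-12)

    def test_spearman_on_monotone_data(self):
        x = np.array([1.0, 2, 3, 4, 5])
        assert exon_intron_correlation(x, np.exp(x), "spearman") == pytest.approx(1.0)

    def test_zero_variance_undefined(self):
        assert math.isnan(
            exon_intron_correlation(np.ones(5), np.array([1.0, 2, 3, 4, 5]))
        )


class TestCorrelationDifferential:
    def test_equal_correlations_p_one(self):
        assert correlation_differential(0.5, 12, 0.5, 46).p_value == 1.0

    def test_fisher_formula_oracle(self):
        # the r = 0.89 (n=12) vs r = 0.33 (n=46) correlation-loss example
        res = correlation_differential(0.89, 12, 0.33, 46)
        z = (math.atanh(0.89) - math.atanh(0.33)) / math.sqrt(1 / 9 + 1 / 43)
        expected = 2 * sps.norm.sf(abs(z))
        assert res.p_value == pytest.approx(expected, abs=1e-10)

    def test_p_shrinks_with_sample_size(self):
        ps = [
            correlation_differential(0.8, n, 0.4, n).p_value
            for n in (5, 10, 20, 40, 80)
        ]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_r_one_is_clipped(self):
        res = correlation_differential(1.0, 10, 0.0, 10)
        assert 0 < res.p_value < 1e-6

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            correlation_differential(0.5, 3, 0.1, 46)


class TestRobustSlope:
    def test_exact_proportionality(self):
        x = np.linspace(1, 5, 12)
        slope, se = robust_slope(x, 3 * x)
        assert slope == pytest.approx(3.0) and se == pytest.approx(0.0, abs=1e-8)

    def test_gross_outliers_resisted(self, rng):
        x = np.linspace(1, 10, 40)
        y = 2 * x + rng.normal(0, 0.05, 40)
        y[:8] += rng.uniform(20, 50, 8)  # 20% gross outliers
        slope, _ = robust_slope(x, y)
        assert slope == pytest.approx(2.0, rel=0.05)

    def test_zero_response(self):
        x = np.linspace(1, 5, 10)
        slope, _ = robust_slope(x, np.zeros(10))
        assert slope == 0.0

    def test_degenerate_predictor(self):
        with pytest.raises(ValueError, match="degenerate"):
            robust_slope(np.ones(10), np.linspace(1, 5, 10))


class TestSlopeDifference:
    def test_equal_slopes(self):
        assert slope_difference_test(2.0, 0.1, 2.0, 0.2) == 1.0

    def test_separated_slopes(self):
        assert slope_difference_test(5.0, 1e-4, 1.0, 1e-4) < 1e-10

    def test_matches_normal_oracle(self, rng):
        for _ in range(20):
            s1, s2 = rng.normal(size=2)
            se1, se2 = rng.uniform(0.05, 1, 2)
            z = (s1 - s2) / math.sqrt(se1**2 + se2**2)
            assert slope_difference_test(s1, se1, s2, se2) == pytest.approx(
                2 * sps.norm.sf(abs(z)), abs=1e-12
            )
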