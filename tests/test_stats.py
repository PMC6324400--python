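"""Statistical core: KDE, trimmed intervals, OVL, SMD and hypothesis tests."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from icuref.exceptions import InputDataError
from icuref.reference import ReferenceInterval, interval_to_distribution
from icuref.stats import (
    analytic_normal_ovl,
    central_interval,
    classify_effect_size,
    estimate_density,
    group_comparison,
    location_shift_test,
    overlap_coefficient,
    silverman_bandwidth,
    smd_vs_reference,
    standardized_mean_difference,
)

finite_samples = st.lists(
    st.floats(-50, 50, allow_nan=False), min_size=5, max_size=40
).filter(lambda xs: len(set(xs)) >= 3)


# ---------------------------------------------------------------- density
class TestDensity:
    def test_normal_peak_height(self):
        rng = np.random.default_rng(1)
        d = estimate_density(rng.normal(0, 1, 100_000))
        peak = np.interp(0.0, d.grid, d.density)
        assert peak == pytest.approx(1 / np.sqrt(2 * np.pi), abs=0.01)

    @pytest.mark.parametrize("seed,n", [(0, 50), (1, 500), (2, 5000)])
    def test_density_integrates_to_one(self, seed, n):
        rng = np.random.default_rng(seed)
        d = estimate_density(np.exp(rng.normal(0, 0.7, n)), support_floor=0.0)
        assert d.integral() == pytest.approx(1.0, abs=1e-3)
        assert d.grid[0] >= 0.0

    def test_two_point_sample_is_bimodal_and_symmetric(self):
        d = estimate_density([0.0, 10.0], grid_points=1001)
        f = lambda t: np.interp(t, d.grid, d.density)
        for t in (1.0, 2.5, 4.0):
            assert f(5 - t) == pytest.approx(f(5 + t), rel=1e-6)
        # two modes at the data points, a trough between
        assert f(0.0) > f(5.0) and f(10.0) > f(5.0)

    def test_requires_two_distinct_values(self):
        with pytest.raises(InputDataError):
            estimate_density([3.0, 3.0, 3.0])
        with pytest.raises(InputDataError):
            estimate_density([1.0, np.nan])

    def test_silverman_bandwidth_matches_formula(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 2, 400)
        s = np.std(x, ddof=1)
        q25, q75 = np.quantile(x, [0.25, 0.75])
        expected = 0.9 * min(s, (q75 - q25) / 1.34) * 400 ** (-0.2)
        assert silverman_bandwidth(x) == pytest.approx(expected, rel=1e-12)


# ------------------------------------------------------- central interval
class TestCentralInterval:
    def test_linear_interpolation_on_integer_fixture(self):
        ci = central_interval(np.arange(1, 1001), trim=0.025)
        assert ci.lower == pytest.approx(25.975, abs=1e-9)
        assert ci.upper == pytest.approx(975.025, abs=1e-9)

    def test_degenerate_constant_sample(self):
        ci = central_interval([7.0] * 10)
        assert (ci.lower, ci.upper) == (7.0, 7.0)

    def test_normal_limit(self):
        rng = np.random.default_rng(5)
        ci = central_interval(rng.normal(0, 1, 100_000), trim=0.025)
        assert ci.lower == pytest.approx(-1.96, abs=0.03)
        assert ci.upper == pytest.approx(1.96, abs=0.03)

    def test_empty_input_rejected(self):
        with pytest.raises(InputDataError):
            central_interval([])


# ----------------------------------------------------------------- OVL
class TestOverlap:
    def test_identical_density_overlap_is_one(self):
        rng = np.random.default_rng(6)
        d = estimate_density(rng.normal(0, 1, 2000))
        assert overlap_coefficient(d, d) == pytest.approx(1.0, abs=1e-6)

    @given(st.integers(0, 2**16), st.floats(0.1, 3.0))
    def test_symmetry(self, seed, shift):
        rng = np.random.default_rng(seed)
        d1 = estimate_density(rng.normal(0, 1, 300), grid_points=128)
        d2 = estimate_density(rng.normal(shift, 1, 300), grid_points=128)
        assert overlap_coefficient(d1, d2) == pytest.approx(
            overlap_coefficient(d2, d1), abs=1e-12
        )

    def test_monotone_decrease_with_location_shift(self):
        rng = np.random.default_rng(7)
        base = rng.normal(0, 1, 4000)
        ref = estimate_density(base)
        ovls = [
            overlap_coefficient(ref, estimate_density(base + delta))
            for delta in (0.0, 0.5, 1.0, 1.5, 2.5)
        ]
        assert all(a > b for a, b in zip(ovls, ovls[1:]))
        assert all(0.0 <= v <= 1.0 for v in ovls)

    @pytest.mark.parametrize(
        "mu2,expected", [(0.0, 1.0), (1.0, 0.6171), (2.0, 0.3173)]
    )
    def test_analytic_normal_ovl_closed_form(self, mu2, expected):
        assert analytic_normal_ovl(0.0, mu2, 1.0) == pytest.approx(expected, abs=5e-5)

    @given(st.floats(-5, 5), st.floats(-5, 5), st.floats(0.1, 4))
    def test_analytic_ovl_symmetric_and_bounded(self, mu1, mu2, sigma):
        v = analytic_normal_ovl(mu1, mu2, sigma)
        assert v == analytic_normal_ovl(mu2, mu1, sigma)
        assert 0.0 <= v <= 1.0

    def test_analytic_ovl_strictly_decreasing_in_separation(self):
        vals = [analytic_normal_ovl(0, d, 1.0) for d in (0, 0.5, 1, 2, 4)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_analytic_ovl_rejects_bad_sigma(self):
        with pytest.raises(ValueError):
            analytic_normal_ovl(0, 1, 0.0)


# ----------------------------------------------------------------- SMD
class TestSMD:
    def test_hand_computed_value(self):
        # pooled SD is 1, mean difference is -2
        assert standardized_mean_difference([0, 1, 2], [2, 3, 4]) == pytest.approx(-2.0)

    def test_identical_groups_zero(self):
        assert standardized_mean_difference([1, 2, 3], [1, 2, 3]) == 0.0

    @given(finite_samples, finite_samples)
    def test_antisymmetry(self, x1, x2):
        try:
            a = standardized_mean_difference(x1, x2)
        except InputDataError:
            return
        b = standardized_mean_difference(x2, x1)
        assert a == pytest.approx(-b, rel=1e-9, abs=1e-12)

    @given(finite_samples, finite_samples, st.floats(0.1, 10), st.floats(-20, 20))
    def test_affine_equivariance(self, x1, x2, a, b):
        try:
            d0 = standardized_mean_difference(x1, x2)
        except InputDataError:
            return
        d1 = standardized_mean_difference(
            [a * v + b for v in x1], [a * v + b for v in x2]
        )
        assert d1 == pytest.approx(d0, rel=1e-6, abs=1e-9)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(InputDataError):
            standardized_mean_difference([1, 1], [1, 1])

    def test_reference_smd_matches_sampled_route_at_equal_n(self):
        dist = interval_to_distribution(ReferenceInterval(3.5, 5.0))
        rng = np.random.default_rng(11)
        x = rng.normal(3.0, 0.6, 30_000)
        ref = rng.normal(dist.mean, dist.sd, 30_000)
        analytic = smd_vs_reference(x, dist)
        sampled = standardized_mean_difference(x, ref)
        assert analytic == pytest.approx(sampled, abs=0.02)

    @pytest.mark.parametrize(
        "smd,band",
        [
            (0.1, "small"), (-0.1, "small"), (0.2, "moderate"), (-0.5, "moderate"),
            (0.8, "moderate"), (1.0, "large"), (-2.03, "large"),
        ],
    )
    def test_effect_size_bands(self, smd, band):
        assert classify_effect_size(smd) == band

    def test_effect_size_requires_finite(self):
        with pytest.raises(ValueError):
            classify_effect_size(float("nan"))


# -------------------------------------------------------- hypothesis tests
class TestLocationShift:
    def test_perfect_symmetry_gives_p_one(self):
        assert location_shift_test([-1, 1, -2, 2, -3, 3], 0.0) == pytest.approx(1.0)

    def test_uniform_exceedance_is_significant(self):
        x = np.linspace(0.5, 3.0, 100)
        assert location_shift_test(x, 0.0) < 0.001

    def test_small_sample_rejected(self):
        with pytest.raises(InputDataError):
            location_shift_test([1, 2, 3, 4, 5], 0.0)

    def test_all_zero_differences_warns_p_one(self):
        with pytest.warns(UserWarning):
            p = location_shift_test([2.0] * 10, 2.0)
        assert p == 1.0

    def test_accepts_reference_distribution(self):
        dist = interval_to_distribution(ReferenceInterval(0.0, 2.0))
        x = np.linspace(2.0, 4.0, 50)  # all above the reference mean of 1
        assert location_shift_test(x, dist) < 0.001


class TestGroupComparison:
    def test_identical_groups_null(self):
        h, p = group_comparison([[1, 2, 3], [1, 2, 3]], kind="continuous")
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_chi2_perfect_separation(self):
        # n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) = 20 for [[10,0],[0,10]]
        chi2, p = group_comparison([[10, 0], [0, 10]], kind="categorical")
        assert chi2 == pytest.approx(20.0)
        assert p < 0.001

    def test_empty_group_rejected(self):
        with pytest.raises(InputDataError):
            group_comparison([[1.0, 2.0], []], kind="continuous")
        with pytest.raises(InputDataError):
            group_comparison([[0, 0], [3, 4]], kind="categorical")

    def test_shifted_groups_detected(self):
        rng = np.random.default_rng(13)
        g1 = rng.normal(0, 1, 200)
        g2 = rng.normal(1.0, 1, 200)
        g3 = rng.normal(0, 1, 200)
        _, p = group_comparison([g1, g2, g3], kind="continuous")
        assert p < 1e-6
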