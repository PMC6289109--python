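import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pdrank as pk
from helpers_oracles import fixed_kde, knn_kde, two_step_kde


def sample_of(*values, **kw):
    return pk.Sample(np.array(values, dtype=float), **kw)


class TestBandwidthRules:
    def test_iqr_rule_formula(self):
        # values {0,1,2,3}: type-7 quartiles 0.75 and 2.25, IQR = 1.5
        s = sample_of(0, 1, 2, 3)
        bw = pk.bandwidth_iqr(s)
        assert bw.iqr == pytest.approx(1.5)
        assert bw.h == pytest.approx(0.79 * 1.5 * 4 ** (-0.2), rel=1e-12)

    def test_iqr_rule_quarter_scaling(self):
        # n = 1024 makes n**(-1/5) exactly 0.25
        rng = np.random.default_rng(0)
        s = pk.Sample(rng.standard_normal(1024))
        bw = pk.bandwidth_iqr(s)
        assert bw.h == pytest.approx(0.79 * s.iqr * 0.25, rel=1e-12)

    def test_normal_reference_formula(self):
        rng = np.random.default_rng(1)
        z = rng.standard_normal(32)
        s = pk.Sample(2.0 * z / np.std(z, ddof=1))  # sigma exactly 2, n = 32
        bw = pk.bandwidth_normal_reference(s)
        assert bw.h == pytest.approx(1.06 * 2.0 * 0.5, rel=1e-12)

    def test_iqr_zero_falls_back_to_sigma(self):
        # three-quarters ties: IQR 0 but sigma positive
        s = sample_of(*([5.0] * 9), 6.0)
        bw = pk.bandwidth_iqr(s)
        assert bw.method == "iqr_rule"
        assert bw.h == pytest.approx(1.06 * s.sigma * 10 ** (-0.2))

    def test_constant_sample_is_degenerate(self):
        s = sample_of(5, 5, 5, 5)
        with pytest.raises(pk.DegenerateSampleError):
            pk.bandwidth_iqr(s)
        with pytest.raises(pk.DegenerateSampleError):
            pk.bandwidth_normal_reference(s)


class TestKernels:
    @pytest.mark.parametrize(
        "kernel_id,u,expected",
        [
            ("gaussian", 0.0, 1.0 / math.sqrt(2 * math.pi)),
            ("gaussian", 1.0, math.exp(-0.5) / math.sqrt(2 * math.pi)),
            ("uniform", 0.0, 0.5),
            ("uniform", 1.0, 0.5),
            ("uniform", 1.2, 0.0),
        ],
    )
    def test_pointwise_values(self, kernel_id, u, expected):
        k = pk.KernelSpec.from_id(kernel_id)
        assert pk.kernel_eval(k, u) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("kernel_id", ["gaussian", "uniform"])
    def test_integrates_to_one_with_matching_roughness(self, kernel_id):
        k = pk.KernelSpec.from_id(kernel_id)
        # integrate over the support; the uniform kernel's jump at +/-1
        # makes an overhanging trapezoid grid systematically biased
        span = 14.0 if kernel_id == "gaussian" else 1.0
        u = np.linspace(-span, span, 200_001)
        vals = pk.kernel_eval(k, u)
        assert np.all(vals >= 0)
        assert np.trapezoid(vals, u) == pytest.approx(1.0, abs=1e-6)
        assert np.trapezoid(vals**2, u) == pytest.approx(k.roughness, abs=1e-6)
        assert np.trapezoid(u**2 * vals, u) == pytest.approx(k.second_moment, abs=1e-4)

    def test_unknown_kernel_rejected(self):
        with pytest.raises(pk.ConfigurationError):
            pk.KernelSpec.from_id("triweight")


class TestFixedBandwidthEstimate:
    def test_single_point_peak(self):
        s = sample_of(0)
        d = pk.density_at(s, [0.0], bw=1.0)
        assert d[0] == pytest.approx(1.0 / math.sqrt(2 * math.pi), rel=1e-12)

    def test_two_point_midpoint(self):
        s = sample_of(-1, 1)
        d = pk.density_at(s, [0.0], bw=1.0)
        assert d[0] == pytest.approx(math.exp(-0.5) / math.sqrt(2 * math.pi), rel=1e-12)

    def test_self_contribution_included(self):
        s = sample_of(0, 10)
        at_obs = pk.density_at(s, [0.0], bw=1.0)[0]
        # own kernel term K(0)/(n h) dominates; the far point adds ~0
        assert at_obs == pytest.approx(0.5 / math.sqrt(2 * math.pi), rel=1e-9)

    def test_empty_points_and_bad_bandwidth(self):
        s = sample_of(0, 1)
        assert pk.density_at(s, [], bw=1.0).size == 0
        with pytest.raises(pk.ParameterError):
            pk.density_at(s, [0.0], bw=-1.0)

    @pytest.mark.parametrize("kernel_id", ["gaussian", "uniform"])
    def test_matches_double_loop_oracle(self, kernel_id):
        rng = np.random.default_rng(11)
        s = pk.Sample(rng.lognormal(0.5, 0.7, 150))
        pts = np.concatenate([s.values[:20], rng.uniform(-1, 8, 30)])
        h = pk.bandwidth_iqr(s).h
        kern = pk.KernelSpec.from_id(kernel_id)
        mine = pk.density_at(s, pts, kern, h)
        ref = fixed_kde(s.values, pts, h, kernel_id)
        np.testing.assert_allclose(mine, ref, atol=1e-12, rtol=0)


class TestKnnEstimate:
    def test_hand_computed_five_points(self):
        s = sample_of(0, 1, 2, 3, 4)
        d = pk.density_knn(s, [2.0], k=2)
        expected = fixed_kde(s.values, [2.0], 1.0)  # d_2(2) = 1
        assert d[0] == pytest.approx(expected[0], rel=1e-12)
        assert d[0] == pytest.approx(0.19817, abs=5e-6)

    def test_k_equal_n_uses_max_distance(self):
        rng = np.random.default_rng(5)
        s = pk.Sample(rng.standard_normal(40))
        pts = rng.uniform(-3, 3, 17)
        np.testing.assert_allclose(
            pk.density_knn(s, pts, k=40),
            knn_kde(s.values, pts, 40),
            atol=1e-12, rtol=0,
        )

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(6)
        s = pk.Sample(rng.gamma(2.0, 1.5, 120))
        pts = np.concatenate([s.values[:15], rng.uniform(0, 12, 25)])
        np.testing.assert_allclose(
            pk.density_knn(s, pts, k=11),
            knn_kde(s.values, pts, 11),
            atol=1e-12, rtol=0,
        )

    def test_k_beyond_n_rejected(self):
        s = sample_of(0, 1, 2)
        with pytest.raises(pk.ParameterError):
            pk.density_knn(s, [1.0], k=4)

    def test_duplicates_substitute_smallest_gap(self, caplog):
        s = sample_of(0, 0, 0, 1, 2)
        with caplog.at_level("WARNING"):
            d = pk.density_knn(s, [0.0], k=2)
        assert np.isfinite(d[0]) and d[0] > 0
        assert any("d_k" in r.message for r in caplog.records)

    def test_all_identical_rejected(self):
        s = sample_of(3, 3, 3)
        with pytest.raises(pk.DegenerateSampleError):
            pk.density_knn(s, [3.0], k=2)


class TestTwoStepEstimate:
    def test_symmetric_sample_gives_symmetric_curve(self):
        s = sample_of(-1, 1)
        left = pk.density_two_step(s, [-0.5])
        right = pk.density_two_step(s, [0.5])
        assert left[0] == pytest.approx(right[0], rel=1e-12)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(8)
        s = pk.Sample(rng.lognormal(1.0, 0.6, 130))
        pts = np.concatenate([s.values[:15], rng.uniform(0, 15, 25)])
        h = pk.bandwidth_iqr(s).h
        np.testing.assert_allclose(
            pk.density_two_step(s, pts),
            two_step_kde(s.values, pts, h),
            atol=1e-12, rtol=0,
        )

    def test_normal_sample_normalises(self):
        rng = np.random.default_rng(9)
        s = pk.Sample(rng.standard_normal(800))
        model = pk.fit_density(s, bandwidth="twostep")
        assert pk.integrate_model(model) == pytest.approx(1.0, abs=0.01)


class TestModelFitting:
    def test_point_densities_are_exact_not_interpolated(self, suite):
        s = suite["skewed_bounded"]
        sub = pk.Sample(s.values[:300], lower_limit=0.0, label=s.label)
        model = pk.fit_density(sub)
        direct = pk.density_at(sub, sub.values, model.kernel, model.bandwidth)
        np.testing.assert_allclose(model.point_densities, direct, atol=1e-12, rtol=0)

    def test_grid_clipped_to_natural_limits(self, suite):
        model = pk.fit_density(suite["zero_inflated"])
        assert model.grid[0] >= 0.0
        assert model.grid[-1] <= 1.0

    def test_normal_closed_form_limit(self, big_normal):
        d = pk.density_at(big_normal, [0.0])
        assert d[0] == pytest.approx(1.0 / math.sqrt(2 * math.pi), abs=0.01)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        a=st.floats(min_value=0.1, max_value=10.0),
        b=st.floats(min_value=-50.0, max_value=50.0),
    )
    def test_translation_scale_equivariance(self, a, b):
        rng = np.random.default_rng(13)
        x = rng.standard_normal(60)
        h = 0.4
        pts = np.array([-1.0, 0.0, 0.7, 2.0])
        base = pk.density_at(pk.Sample(x), pts, bw=h)
        moved = pk.density_at(pk.Sample(a * x + b), a * pts + b, bw=a * h)
        np.testing.assert_allclose(moved, base / a, atol=1e-10, rtol=1e-10)


class TestDensityVariance:
    def test_zero_density_zero_variance(self):
        v = pk.density_variance(0.0, n=50, h=0.5)
        assert v.var == 0.0

    def test_gaussian_roughness_value(self):
        v = pk.density_variance(0.4, n=100, h=0.3)
        assert v.var == pytest.approx(0.4 * 0.2820948 / 30.0, rel=1e-5)

    def test_scales_inversely_with_n(self):
        v100 = pk.density_variance(0.4, n=100, h=0.3)
        v1000 = pk.density_variance(0.4, n=1000, h=0.3)
        assert v1000.var == pytest.approx(v100.var / 10.0, rel=1e-12)

    def test_printed_second_moment_variant_selectable(self):
        v = pk.density_variance(0.4, n=100, h=0.3, constant="second_moment")
        assert v.var == pytest.approx(0.4 * 1.0 / 30.0, rel=1e-12)

    def test_difference_test_decisions(self):
        va = pk.density_variance(0.4, n=100, h=0.3)
        sig, z = pk.density_difference_test(va, va)
        assert not sig and z == 0.0

        a = pk.DensityVariance(fhat=0.4, var=1e-4, n=100, h=0.3)
        b = pk.DensityVariance(fhat=0.3, var=1e-4, n=100, h=0.3)
        sig, z = pk.density_difference_test(a, b, alpha=0.05)
        assert sig
        assert z == pytest.approx(0.1 / math.sqrt(2e-4), rel=1e-9)

        zero = pk.DensityVariance(fhat=0.2, var=0.0, n=10, h=0.1)
        assert pk.density_difference_test(zero, zero) == (False, 0.0)
        other = pk.DensityVariance(fhat=0.3, var=0.0, n=10, h=0.1)
        with pytest.raises(pk.DegenerateSampleError):
            pk.density_difference_test(zero, other)
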