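"""Analytic ERF ratios, side-kernel rule, and the gradient probe."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mismatch.erf import (ErfRatioInputs, binomial_path_weight,
                          erf_ratio_nasb, erf_ratio_pasb,
                          measure_empirical_erf, minimal_side_kernel)
from mismatch.nn import Tensor, conv_nd


class TestAnalyticRatios:
    def test_dilating_ratio_closed_form(self):
        got = erf_ratio_pasb(ErfRatioInputs(K=3, K_side=9, n=1))
        assert got == pytest.approx(3 * np.sqrt(2 / 3), abs=1e-12)

    def test_equal_kernels_deep_limit_is_one(self):
        assert erf_ratio_pasb(ErfRatioInputs(K=3, K_side=3, n=10**9)) == pytest.approx(1.0, abs=1e-6)

    def test_shallow_infimum_factor(self):
        # at vanishing depth the correction tends to sqrt(0.5)
        shallow = (9 / 3) * np.sqrt(0.5)
        assert shallow == pytest.approx(2.121, abs=1e-3)
        assert erf_ratio_pasb(ErfRatioInputs(K=3, K_side=9, n=1)) > shallow

    @given(n=st.integers(min_value=1, max_value=500))
    @settings(deadline=None, max_examples=50)
    def test_dilating_ratio_increases_with_depth(self, n):
        lo = erf_ratio_pasb(ErfRatioInputs(K=3, K_side=9, n=n))
        hi = erf_ratio_pasb(ErfRatioInputs(K=3, K_side=9, n=n + 1))
        assert hi > lo

    def test_eroding_ratio_closed_form(self):
        expected = 0.25 * np.sqrt(1 / 3) + 0.5 * np.sqrt(2 / 3) + 0.25
        assert erf_ratio_nasb(1) == pytest.approx(expected, abs=1e-12)
        assert erf_ratio_nasb(1) == pytest.approx(0.8026, abs=1e-4)

    @given(n=st.integers(min_value=1, max_value=10**6))
    @settings(deadline=None, max_examples=100)
    def test_eroding_ratio_below_one_and_monotone(self, n):
        assert erf_ratio_nasb(n) < 1.0
        assert erf_ratio_nasb(n + 1) > erf_ratio_nasb(n)

    def test_eroding_ratio_approaches_one(self):
        assert erf_ratio_nasb(10**8) == pytest.approx(1.0, abs=1e-3)

    @pytest.mark.parametrize("bad", [dict(K=2), dict(K=-3), dict(n=0), dict(p=1.5)])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            ErfRatioInputs(**bad)

    @pytest.mark.parametrize("n", [0, -1])
    def test_eroding_ratio_needs_positive_depth(self, n):
        with pytest.raises(ValueError):
            erf_ratio_nasb(n)


class TestSideKernelRule:
    @pytest.mark.parametrize("K, doubling, expected", [
        (3, True, 9),    # the published design point
        (1, False, 3),   # smallest odd integer > 1.414
        (3, False, 5),   # smallest odd integer > 4.243
        (5, True, 15),
        (1, True, 3),
    ])
    def test_minimal_side_kernel(self, K, doubling, expected):
        assert minimal_side_kernel(K, doubling=doubling) == expected

    @pytest.mark.parametrize("K", [0, -1, 4])
    def test_rejects_even_or_nonpositive(self, K):
        with pytest.raises(ValueError):
            minimal_side_kernel(K)

    @given(K=st.integers(min_value=1, max_value=49).filter(lambda k: k % 2 == 1),
           n=st.integers(min_value=1, max_value=100))
    @settings(deadline=None, max_examples=60)
    def test_minimal_kernel_guarantees_enlargement(self, K, n):
        k_side = minimal_side_kernel(K, doubling=False)
        assert erf_ratio_pasb(ErfRatioInputs(K=K, K_side=k_side, n=n)) > 1.0


class TestBinomialPathWeights:
    @pytest.mark.parametrize("N, k, p, expected", [
        (2, 1, 0.5, 0.5),
        (2, 0, 0.5, 0.25),
        (2, 2, 0.5, 0.25),
    ])
    def test_two_layer_weights(self, N, k, p, expected):
        assert binomial_path_weight(N, k, p) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("N", range(1, 7))
    @pytest.mark.parametrize("p", [0.1, 0.3, 0.5, 0.7, 0.9])
    def test_weights_sum_to_one(self, N, p):
        total = sum(binomial_path_weight(N, k, p) for k in range(N + 1))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_out_of_range_k(self):
        with pytest.raises(ValueError):
            binomial_path_weight(2, 3, 0.5)
        with pytest.raises(ValueError):
            binomial_path_weight(2, -1, 0.5)


def _linear_conv_net(weights, dilations):
    """Bias-free conv stack used as a receptive-field oracle subject."""
    tensors = [Tensor(w) for w in weights]

    def run(x):
        for w, d in zip(tensors, dilations):
            x = conv_nd(x, w, dilation=d)
        return x

    return run


class TestGradientProbe:
    def footprint(self, profile):
        rows, cols = np.nonzero(profile.gradient_map)
        return (rows.max() - rows.min() + 1, cols.max() - cols.min() + 1)

    def test_single_conv_support_is_kernel_footprint(self):
        w = np.ones((1, 1, 3, 3))
        prof = measure_empirical_erf(_linear_conv_net([w], [1]), (1, 9, 9))
        assert prof.support_area == 9
        assert self.footprint(prof) == (3, 3)

    def test_two_convs_compose_to_5x5(self):
        w = np.ones((1, 1, 3, 3))
        prof = measure_empirical_erf(_linear_conv_net([w, w], [1, 1]), (1, 11, 11))
        assert self.footprint(prof) == (5, 5)
        assert prof.support_area == 25

    def test_dilated_conv_spans_11x11_extent(self):
        w = np.ones((1, 1, 3, 3))
        prof = measure_empirical_erf(_linear_conv_net([w], [5]), (1, 15, 15))
        assert self.footprint(prof) == (11, 11)
        assert prof.support_area == 9  # sparse taps

    def test_three_layer_footprint_matches_brute_force_oracle(self):
        # oracle: nonzeros of the composed kernel, computed by convolving
        # kernel indicator masks (receptive-field composition)
        rng = np.random.default_rng(3)
        shapes = [(2, 1, 3, 3), (2, 2, 3, 3), (1, 2, 3, 3)]
        dil = [1, 2, 1]
        weights = [rng.normal(size=s) for s in shapes]
        from scipy.signal import convolve2d
        oracle = np.ones((1, 1))
        for s, d in zip(shapes, dil):
            k = s[-1]
            ind = np.zeros((d * (k - 1) + 1,) * 2)
            ind[::d, ::d] = 1.0
            oracle = convolve2d(oracle, ind)
        prof = measure_empirical_erf(
            _linear_conv_net(weights, dil), (1, 15, 15), probe_threshold=1e-9)
        assert self.footprint(prof) == oracle.shape
        # support cannot exceed the oracle's nonzero taps
        assert prof.support_area <= int(np.count_nonzero(oracle))

    def test_even_spatial_dims_rejected(self):
        w = np.ones((1, 1, 3, 3))
        with pytest.raises(ValueError):
            measure_empirical_erf(_linear_conv_net([w], [1]), (1, 8, 8))

    def test_disconnected_network_signals_failure(self):
        w = np.zeros((1, 1, 3, 3))
        with pytest.raises(ArithmeticError):
            measure_empirical_erf(_linear_conv_net([w], [1]), (1, 9, 9))
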