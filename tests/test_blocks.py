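"""Unit tests for the convolution, dilated-Inception and attention operators."""

import numpy as np
import pytest

from pestseg import (
    ConvKernelSpec,
    InceptionConfig,
    attention_forward,
    attention_weights,
    classical_conv,
    dilated_conv,
    dilated_inception_forward,
    effective_kernel_size,
    init_attention_params,
    init_inception_params,
    receptive_field_gain,
    zero_inflate_kernel,
)
from pestseg.blocks import AttentionParams
from pestseg._tensor import Tensor


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def loop_conv(image, kernel, rate=1):
    """Direct double-loop evaluation of the (dilated) convolution sum."""
    h, w, cin = image.shape
    k = kernel.shape[0]
    cout = kernel.shape[3]
    c = k // 2
    out = np.zeros((h, w, cout))
    for y in range(h):
        for x in range(w):
            for i in range(k):
                for j in range(k):
                    yy = y + rate * (i - c)
                    xx = x + rate * (j - c)
                    if 0 <= yy < h and 0 <= xx < w:
                        out[y, x] += image[yy, xx] @ kernel[i, j]
    return out


# ---------------------------------------------------------------------------
# classical / dilated convolution
# ---------------------------------------------------------------------------

class TestConvolution:
    def test_impulse_response_spreads_kernel(self):
        img = np.zeros((9, 9, 1))
        img[4, 4, 0] = 1.0
        out = classical_conv(img, np.ones((3, 3, 1, 1)))
        expect = np.zeros((9, 9))
        expect[3:6, 3:6] = 1.0
        np.testing.assert_allclose(out[:, :, 0], expect)

    def test_zero_image_maps_to_zero(self, rng):
        out = classical_conv(np.zeros((8, 8, 2)), rng.normal(size=(3, 3, 2, 3)))
        assert np.all(out == 0.0)

    def test_matches_loop_oracle(self, rng):
        img = rng.normal(size=(8, 8, 2))
        ker = rng.normal(size=(3, 3, 2, 3))
        np.testing.assert_allclose(classical_conv(img, ker), loop_conv(img, ker), atol=1e-6)

    def test_rate_one_equals_classical(self, rng):
        img = rng.normal(size=(10, 10, 2))
        ker = rng.normal(size=(3, 3, 2, 2))
        np.testing.assert_array_equal(dilated_conv(img, ker, rate=1), classical_conv(img, ker))

    def test_dilated_impulse_hits_spread_stencil(self):
        img = np.zeros((9, 9, 1))
        img[4, 4, 0] = 1.0
        out = dilated_conv(img, np.ones((3, 3, 1, 1)), rate=2)[:, :, 0]
        nz = {(int(y), int(x)) for y, x in zip(*np.nonzero(out))}
        assert nz == {(4 + dy, 4 + dx) for dy in (-2, 0, 2) for dx in (-2, 0, 2)}

    def test_dilated_matches_loop_oracle(self, rng):
        img = rng.normal(size=(9, 9, 1))
        ker = rng.normal(size=(3, 3, 1, 2))
        np.testing.assert_allclose(
            dilated_conv(img, ker, rate=2), loop_conv(img, ker, rate=2), atol=1e-6
        )

    @pytest.mark.parametrize("k", [1, 3, 5])
    @pytest.mark.parametrize("rate", [1, 2, 3, 4])
    def test_equals_classical_with_zero_inflated_kernel(self, rng, k, rate):
        img = rng.normal(size=(16, 16, 2))
        ker = rng.normal(size=(k, k, 2, 2))
        dil = dilated_conv(img, ker, rate=rate)
        inf = classical_conv(img, zero_inflate_kernel(ker, rate))
        assert np.abs(dil - inf).max() < 1e-6

    def test_linearity_in_image_and_kernel(self, rng):
        img1, img2 = rng.normal(size=(2, 8, 8, 1))
        ker = rng.normal(size=(3, 3, 1, 1))
        lhs = classical_conv(2 * img1 + img2, ker)
        rhs = 2 * classical_conv(img1, ker) + classical_conv(img2, ker)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_even_kernel_rejected(self, rng):
        with pytest.raises(ValueError, match="odd"):
            classical_conv(rng.normal(size=(8, 8, 1)), rng.normal(size=(4, 4, 1, 1)))
        with pytest.raises(ValueError):
            ConvKernelSpec(k=4)

    def test_rate_below_one_rejected(self, rng):
        with pytest.raises(ValueError, match="rate"):
            dilated_conv(rng.normal(size=(8, 8, 1)), rng.normal(size=(3, 3, 1, 1)), rate=0)

    def test_weight_count_is_k_squared_for_every_rate(self):
        # dilation spreads the stencil but adds no trainable weights
        for rate in (1, 2, 3, 4):
            spec = ConvKernelSpec(k=3, rate=rate)
            assert spec.k**2 == 9
            assert spec.effective_size == 3 + 2 * (rate - 1)


class TestReceptiveFieldAlgebra:
    @pytest.mark.parametrize("k,r,expect", [(3, 1, 3), (3, 2, 5), (3, 4, 9), (5, 3, 13)])
    def test_effective_kernel_size(self, k, r, expect):
        assert effective_kernel_size(k, r) == expect

    @pytest.mark.parametrize("k", [1, 3, 5, 7, 9])
    def test_rate_one_is_identity(self, k):
        assert effective_kernel_size(k, 1) == k

    @pytest.mark.parametrize("k", [3, 5])
    def test_strictly_increasing_in_rate(self, k):
        sizes = [effective_kernel_size(k, r) for r in range(1, 6)]
        assert all(a < b for a, b in zip(sizes, sizes[1:]))

    def test_gain_values(self):
        assert receptive_field_gain(3, 1) == 1.0
        assert receptive_field_gain(3, 2) == pytest.approx((5 / 3) ** 2)
        assert receptive_field_gain(5, 3) == pytest.approx(6.76)


# ---------------------------------------------------------------------------
# dilated Inception block
# ---------------------------------------------------------------------------

class TestDilatedInception:
    def make(self, rng, cin=3, cout=8, **kw):
        cfg = InceptionConfig(**kw).resolve(cout)
        params = init_inception_params(cfg, cin, rng)
        return cfg, params

    @pytest.mark.parametrize("h,w", [(8, 8), (12, 20), (9, 33)])
    def test_output_shape_is_hw_out_channels(self, rng, h, w):
        cfg, params = self.make(rng, cin=3, cout=6)
        out = dilated_inception_forward(rng.normal(size=(h, w, 3)), cfg, params)
        assert out.shape == (h, w, 6)
        assert np.all(np.isfinite(out))

    def test_zero_input_zero_bias_gives_zero(self, rng):
        cfg, params = self.make(rng, cin=2, cout=4)
        out = dilated_inception_forward(np.zeros((8, 8, 2)), cfg, params)
        np.testing.assert_array_equal(out, 0.0)

    def test_gap_path_restores_pooled_constant(self, rng):
        # pass-through 1x1 weights: global mean of a constant-c map comes
        # back as a constant-c map after the upsample
        c = 0.7
        cfg = InceptionConfig(bottleneck_channels=1).resolve(1)
        params = init_inception_params(cfg, 1, rng)
        params["gap.conv.w"].data[:] = 1.0
        params["gap.conv.b"].data[:] = 0.0
        _, parts = dilated_inception_forward(
            np.full((4, 4, 1), c), cfg, params, return_parts=True
        )
        np.testing.assert_allclose(parts["G_gap"], np.full((4, 4, 1), c), atol=1e-12)

    def test_channel_mismatch_raises(self, rng):
        cfg, params = self.make(rng, cin=3, cout=4)
        with pytest.raises(ValueError, match="channels"):
            dilated_inception_forward(rng.normal(size=(8, 8, 5)), cfg, params)

    def test_exactly_three_branches_enforced(self):
        with pytest.raises(ValueError, match="three"):
            InceptionConfig(branch_rates=(1, 2), branch_kernels=(3, 3))

    def test_footprints_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            InceptionConfig(branch_rates=(2, 2, 2))
        # classic multi-kernel geometry is valid: footprints 1 < 3 < 5
        InceptionConfig(branch_rates=(1, 1, 1), branch_kernels=(1, 3, 5))

    def test_additive_fusion_mode(self, rng):
        cfg, params = self.make(rng, cin=3, cout=4, fusion="add")
        out = dilated_inception_forward(rng.normal(size=(8, 8, 3)), cfg, params)
        assert out.shape == (8, 8, 4)

    def test_dilation_rates_add_no_parameters(self, rng):
        def n_params(rates):
            cfg = InceptionConfig(branch_rates=rates).resolve(8)
            p = init_inception_params(cfg, 4, np.random.default_rng(0))
            return sum(v.data.size for v in p.values())

        assert n_params((1, 2, 3)) == n_params((2, 4, 6)) == n_params((1, 3, 5))


# ---------------------------------------------------------------------------
# attention gate
# ---------------------------------------------------------------------------

def hand_attention(g, params):
    """Independent plain-numpy evaluation of the channel-attention gate."""
    gmp = g.max(axis=(0, 1))
    gap = g.mean(axis=(0, 1))

    def mlp(v):
        hidden = np.maximum(v @ params.fc1_w.data + params.fc1_b.data, 0.0)
        return hidden @ params.fc2_w.data + params.fc2_b.data

    s_a = 1.0 / (1.0 + np.exp(-(mlp(gmp) + mlp(gap))))
    return g * s_a[None, None, :], s_a


class TestAttention:
    def test_zero_input_zero_bias_gives_half_weights(self, rng):
        params = init_attention_params(8, 8, rng)
        g = np.zeros((5, 5, 8))
        np.testing.assert_array_equal(attention_weights(g, params), 0.5)
        np.testing.assert_array_equal(attention_forward(g, params), 0.0)

    def test_weights_in_open_unit_interval_and_contractive(self, rng):
        for _ in range(20):
            c = int(rng.choice([4, 8, 12]))
            params = init_attention_params(c, 4, rng)
            g = rng.normal(size=(6, 7, c)) * 3
            s_a = attention_weights(g, params)
            assert np.all(s_a > 0) and np.all(s_a < 1)
            out = attention_forward(g, params)
            assert np.all(np.abs(out) <= np.abs(g) + 1e-15)
            assert np.abs(out).max() <= np.abs(g).max()

    def test_matches_hand_evaluation_on_2x2x2(self, rng):
        params = AttentionParams(
            fc1_w=Tensor(np.array([[0.5], [-0.3]])),
            fc1_b=Tensor(np.array([0.1])),
            fc2_w=Tensor(np.array([[1.2, -0.7]])),
            fc2_b=Tensor(np.array([0.05, -0.2])),
            reduction=2,
        )
        g = np.array(
            [[[0.2, -0.4], [1.0, 0.3]], [[-0.5, 0.8], [0.1, -0.9]]]
        )
        expect_out, expect_sa = hand_attention(g, params)
        np.testing.assert_allclose(attention_weights(g, params), expect_sa, atol=1e-6)
        np.testing.assert_allclose(attention_forward(g, params), expect_out, atol=1e-6)

    def test_fc_stack_is_shared_between_branches(self, rng):
        params = init_attention_params(4, 2, rng)
        # a constant map has gmp == gap, so both branches produce the same
        # excitation and S_a == sigmoid(2 * mlp(c))
        g = np.full((3, 3, 4), 1.3)
        _, s_hand = hand_attention(g, params)
        np.testing.assert_allclose(attention_weights(g, params), s_hand, atol=1e-12)

    def test_reduction_must_divide_channels(self, rng):
        with pytest.raises(ValueError, match="divisor"):
            init_attention_params(6, 4, rng)
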