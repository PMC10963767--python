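import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import (
    attention_naive,
    conv2d_naive,
    cse_naive,
    finite_difference_grad,
    gated_mlp_naive,
    pscse_naive,
    sse_naive,
    vector_axial_naive,
    _attn_params,
)
from woundfusion.autodiff import Tensor
from woundfusion.blocks import (
    AdaptiveGatedMLP,
    AxialAttention,
    ChannelSE,
    ConvBlock,
    ParallelSCSE,
    SpatialSE,
    VectorAxialAttention,
)


def _rand(rng, *shape):
    return rng.normal(size=shape)


class TestConvBlock:
    def test_matches_naive_cross_correlation(self, rng):
        block = ConvBlock(3, 4, rng, kernel_size=3)
        x = _rand(rng, 2, 3, 5, 6)
        out = block(Tensor(x)).data
        ref = np.maximum(
            conv2d_naive(x, block.conv.weight.data, block.conv.bias.data, padding=1), 0.0
        )
        np.testing.assert_allclose(out, ref, atol=1e-5)

    def test_relu_kills_negative_input_under_identity_kernel(self, rng):
        block = ConvBlock(1, 1, rng, kernel_size=1)
        block.conv.weight.data[:] = 1.0  # 1x1 identity
        block.conv.bias.data[:] = 0.0
        x = -np.abs(_rand(rng, 1, 1, 4, 4))
        assert np.all(block(Tensor(x)).data == 0.0)
        y = np.abs(_rand(rng, 1, 1, 4, 4))
        np.testing.assert_allclose(block(Tensor(y)).data, y)

    def test_channel_mismatch_raises(self, rng):
        block = ConvBlock(3, 4, rng)
        with pytest.raises(ValueError, match="channel"):
            block(Tensor(np.zeros((1, 2, 4, 4))))


class TestSqueezeExcitation:
    def test_cse_matches_loop_oracle(self, rng):
        mod = ChannelSE(6, rng, r=2)
        x = _rand(rng, 2, 6, 4, 5)
        ref = cse_naive(
            x, mod.fc1.weight.data, mod.fc1.bias.data, mod.fc2.weight.data, mod.fc2.bias.data
        )
        np.testing.assert_allclose(mod(Tensor(x)).data, ref, atol=1e-5)

    def test_sse_matches_loop_oracle(self, rng):
        mod = SpatialSE(5, rng)
        x = _rand(rng, 2, 5, 3, 4)
        ref = sse_naive(x, mod.proj.weight.data, mod.proj.bias.data)
        np.testing.assert_allclose(mod(Tensor(x)).data, ref, atol=1e-5)

    def test_saturated_gates(self, rng):
        mod = ChannelSE(4, rng, r=2)
        x = np.abs(_rand(rng, 1, 4, 3, 3))
        mod.fc2.weight.data[:] = 0.0
        mod.fc2.bias.data[:] = 50.0  # sigmoid -> 1
        np.testing.assert_allclose(mod(Tensor(x)).data, x, atol=1e-6)
        mod.fc2.bias.data[:] = -50.0  # sigmoid -> 0
        np.testing.assert_allclose(mod(Tensor(x)).data, 0.0, atol=1e-6)

    def test_sse_zero_projection_halves_input(self, rng):
        mod = SpatialSE(3, rng)
        mod.proj.weight.data[:] = 0.0
        mod.proj.bias.data[:] = 0.0
        x = _rand(rng, 1, 3, 4, 4)
        np.testing.assert_allclose(mod(Tensor(x)).data, x / 2, atol=1e-12)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(
        c=st.integers(1, 8), h=st.integers(1, 8), w=st.integers(1, 8),
        seed=st.integers(0, 100),
    )
    def test_gates_bound_outputs_elementwise(self, c, h, w, seed):
        rng = np.random.default_rng(seed)
        x = _rand(rng, 1, c, h, w)
        for mod in (ChannelSE(c, rng, r=2), SpatialSE(c, rng)):
            out = mod(Tensor(x)).data
            assert out.shape == x.shape
            assert np.all(np.abs(out) <= np.abs(x) + 1e-12)
        merged = ParallelSCSE(c, rng, r=2)(Tensor(x)).data
        assert merged.shape == x.shape
        assert np.all(np.abs(merged) <= 3 * np.abs(x) + 1e-12)


class TestParallelSCSE:
    def test_matches_composed_oracle(self, rng):
        mod = ParallelSCSE(4, rng, r=2)
        x = _rand(rng, 2, 4, 3, 3)
        ref = pscse_naive(
            x,
            (mod.cse.fc1.weight.data, mod.cse.fc1.bias.data,
             mod.cse.fc2.weight.data, mod.cse.fc2.bias.data),
            (mod.sse.proj.weight.data, mod.sse.proj.bias.data),
        )
        np.testing.assert_allclose(mod(Tensor(x)).data, ref, atol=1e-5)

    def test_identical_gate_effects_give_three_a(self, rng):
        mod = ParallelSCSE(3, rng, r=1)
        # force both gates to exactly 0.5: a == b == x/2, merge = max(a,a)+2a = 3a
        mod.cse.fc2.weight.data[:] = 0.0
        mod.cse.fc2.bias.data[:] = 0.0
        mod.sse.proj.weight.data[:] = 0.0
        mod.sse.proj.bias.data[:] = 0.0
        x = _rand(rng, 1, 3, 4, 4)
        np.testing.assert_allclose(mod(Tensor(x)).data, 3 * (x / 2), atol=1e-12)

    def test_zero_input_gives_zero(self, rng):
        mod = ParallelSCSE(3, rng)
        assert np.all(mod(Tensor(np.zeros((1, 3, 4, 4)))).data == 0.0)

    def test_alternative_merges(self, rng):
        x = _rand(rng, 1, 4, 3, 3)
        for merge in ("max", "add"):
            mod = ParallelSCSE(4, rng, r=2, merge=merge)
            a = mod.cse(Tensor(x)).data
            b = mod.sse(Tensor(x)).data
            ref = np.maximum(a, b) if merge == "max" else a + b
            np.testing.assert_allclose(mod(Tensor(x)).data, ref, atol=1e-12)
        with pytest.raises(ValueError, match="merge"):
            ParallelSCSE(4, rng, merge="mystery")


class TestAxialAttention:
    def test_single_row_map_equals_full_attention(self, rng):
        # H == 1: width-axis attention degenerates to full attention over W tokens
        mod = AxialAttention(3, rng)
        x = _rand(rng, 1, 3, 1, 6)
        out = mod(Tensor(x), axis="width").data
        tokens = x[0, :, 0, :].T  # (W, C)
        ref = attention_naive(tokens, *_attn_params(mod))
        np.testing.assert_allclose(out[0, :, 0, :].T, ref, atol=1e-5)

    def test_single_token_output_is_value_plus_residual(self, rng):
        mod = AxialAttention(4, rng)
        x = _rand(rng, 1, 1, 4)
        out = mod(Tensor(x)).data
        v = x[0] @ mod.wv.weight.data + mod.wv.bias.data
        np.testing.assert_allclose(out[0], v + x[0], atol=1e-10)

    def test_slice_equivariance_along_non_attended_axis(self, rng):
        mod = AxialAttention(3, rng)
        x = _rand(rng, 1, 3, 5, 4)
        out = mod(Tensor(x), axis="width").data
        perm = rng.permutation(5)
        out_perm = mod(Tensor(x[:, :, perm, :]), axis="width").data
        np.testing.assert_allclose(out_perm, out[:, :, perm, :], atol=1e-10)

    def test_height_and_width_axes_are_transposes(self, rng):
        mod = AxialAttention(3, rng)
        x = _rand(rng, 2, 3, 4, 5)
        h_out = mod(Tensor(x), axis="height").data
        w_out = mod(Tensor(x.transpose(0, 1, 3, 2)), axis="width").data
        np.testing.assert_allclose(h_out, w_out.transpose(0, 1, 3, 2), atol=1e-10)

    def test_invalid_axis_raises(self, rng):
        mod = AxialAttention(3, rng)
        with pytest.raises(ValueError):
            mod(Tensor(np.zeros((1, 3, 4, 4))), axis="diagonal")

    def test_vector_axial_matches_naive_grid_walk(self, rng):
        mod = VectorAxialAttention(10, rng)  # pads 10 -> 4x4 grid
        x = _rand(rng, 3, 10)
        out = mod(Tensor(x)).data
        for i in range(3):
            np.testing.assert_allclose(out[i], vector_axial_naive(x[i], mod), atol=1e-5)

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(c=st.integers(1, 8), h=st.integers(1, 8), w=st.integers(1, 8))
    def test_shape_preservation_on_maps(self, c, h, w):
        rng = np.random.default_rng(c * 100 + h * 10 + w)
        mod = AxialAttention(c, rng)
        x = _rand(rng, 1, c, h, w)
        for axis in ("height", "width"):
            assert mod(Tensor(x), axis=axis).data.shape == x.shape


class TestAdaptiveGatedMLP:
    def test_matches_step_by_step_oracle(self, rng):
        mod = AdaptiveGatedMLP(20, rng, hidden=8, out_features=5)
        loc = np.zeros((2, 20))
        loc[0, 3] = 1.0
        loc[1, 17] = 1.0
        out = mod(Tensor(loc)).data
        for i in range(2):
            np.testing.assert_allclose(out[i], gated_mlp_naive(loc[i], mod), atol=1e-5)

    def test_closed_gate_blocks_location_signal(self, rng):
        mod = AdaptiveGatedMLP(20, rng, hidden=8, out_features=5)
        mod.force_gate(-1e9)
        a = mod(Tensor(np.eye(20)[[0]])).data
        b = mod(Tensor(np.eye(20)[[13]])).data
        np.testing.assert_allclose(a, b, atol=1e-12)  # only W_out bias survives
        np.testing.assert_allclose(a[0], mod.w_out.bias.data, atol=1e-12)

    def test_open_gate_passes_u1_through_output_projection(self, rng):
        mod = AdaptiveGatedMLP(20, rng, hidden=8, out_features=5)
        mod.force_gate(1e9)
        loc = np.eye(20)[[7]]
        u = np.maximum(loc @ mod.w_in.weight.data + mod.w_in.bias.data, 0.0)
        expected = u[:, : mod.half] @ mod.w_out.weight.data + mod.w_out.bias.data
        np.testing.assert_allclose(mod(Tensor(loc)).data, expected, atol=1e-10)

    def test_length_mismatch_raises(self, rng):
        mod = AdaptiveGatedMLP(20, rng, hidden=8)
        with pytest.raises(ValueError):
            mod(Tensor(np.zeros((1, 21))))


class TestDifferentiability:
    """Finite-difference gradient checks on tiny instances."""

    @pytest.mark.parametrize("which", ["conv", "cse", "sse", "pscse", "axial", "gmlp"])
    def test_autodiff_matches_finite_differences(self, which, rng):
        if which == "conv":
            mod, x = ConvBlock(2, 2, rng), _rand(rng, 1, 2, 3, 3)
        elif which == "cse":
            mod, x = ChannelSE(3, rng, r=2), _rand(rng, 1, 3, 2, 2)
        elif which == "sse":
            mod, x = SpatialSE(3, rng), _rand(rng, 1, 3, 2, 2)
        elif which == "pscse":
            mod, x = ParallelSCSE(3, rng, r=2), _rand(rng, 1, 3, 2, 2)
        elif which == "axial":
            mod, x = AxialAttention(3, rng), _rand(rng, 1, 4, 3)
        else:
            mod, x = AdaptiveGatedMLP(6, rng, hidden=4, out_features=3), _rand(rng, 1, 6)
        probe = rng.normal(size=mod(Tensor(x)).shape)

        def f(arr):
            return float((mod(Tensor(arr)).data * probe).sum())

        t = Tensor(x.copy(), requires_grad=True)
        (mod(t) * Tensor(probe)).sum().backward()
        fd = finite_difference_grad(f, x.copy())
        denom = np.maximum(np.abs(fd), 1e-3)
        assert np.max(np.abs(t.grad - fd) / denom) < 1e-3
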