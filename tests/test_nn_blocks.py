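import numpy as np
import pytest
from scipy.signal import correlate2d

from ctdenoise.autodiff import Tensor
from ctdenoise.nn_blocks import (
    BlockConfig,
    CSEGate,
    ConvBlock,
    HFSModule,
    ResidualBlock,
    SCSEBlock,
    SSEGate,
    blurpool,
    make_blur_kernel,
    pixel_shuffle,
    pixel_unshuffle,
)


class TestBlurKernel:
    def test_size_two(self):
        assert np.allclose(make_blur_kernel(2), np.full((2, 2), 0.25))

    def test_size_three_binomial(self):
        expected = np.outer([1, 2, 1], [1, 2, 1]) / 16.0
        assert np.allclose(make_blur_kernel(3), expected)

    @pytest.mark.parametrize("size", [2, 3, 4, 5])
    def test_normalized_and_separable(self, size):
        k = make_blur_kernel(size)
        assert abs(k.sum() - 1.0) < 1e-12
        assert np.all(k >= 0)
        # rank-1: outer product of its first row/col up to scale
        u, s, vt = np.linalg.svd(k)
        assert s[1] < 1e-12

    def test_unsupported_size(self):
        with pytest.raises(ValueError):
            make_blur_kernel(7)


class TestBlurPool:
    def test_constant_preserved(self):
        out = blurpool(np.ones((1, 1, 8, 8)), stride=2, blur_size=3)
        assert out.shape == (1, 1, 4, 4)
        assert np.allclose(out.numpy(), 1.0)

    def test_output_size_ceil(self):
        out = blurpool(np.ones((1, 2, 9, 7)), stride=2, blur_size=3)
        assert out.shape == (1, 2, 5, 4)

    def test_impulse_matches_dense_oracle(self):
        x = np.zeros((9, 9))
        x[4, 4] = 1.0
        k = make_blur_kernel(3)
        dense = correlate2d(np.pad(x, 1, mode="reflect"), k, mode="valid")
        expected = dense[::2, ::2]
        out = blurpool(x.reshape(1, 1, 9, 9), stride=2, blur_size=3)
        assert np.allclose(out.numpy()[0, 0], expected, atol=1e-12)

    def test_shift_consistency_beats_naive(self, rng):
        """The anti-aliased pool varies less under 1-pixel shifts than naive
        stride-2 subsampling (the property it exists to provide)."""
        def shift_error(pool):
            errs = []
            for _ in range(100):
                x = rng.normal(size=(32, 32))
                a = pool(x)
                b = pool(np.roll(x, 1, axis=1))
                errs.append(np.sqrt(np.mean((a - b) ** 2)))
            return np.mean(errs)

        blur_err = shift_error(
            lambda x: blurpool(x.reshape(1, 1, 32, 32)).numpy()[0, 0]
        )
        naive_err = shift_error(lambda x: x[::2, ::2])
        assert blur_err < naive_err

    def test_invalid_stride(self):
        with pytest.raises(ValueError):
            blurpool(np.ones((1, 1, 8, 8)), stride=0)


class TestPixelShuffle:
    def test_r1_identity(self, rng):
        x = rng.normal(size=(1, 3, 4, 4))
        assert np.array_equal(pixel_shuffle(x, 1).numpy(), x)

    def test_r2_index_map(self):
        x = np.array([1.0, 2.0, 3.0, 4.0]).reshape(1, 4, 1, 1)
        out = pixel_shuffle(x, 2).numpy()
        assert out.shape == (1, 1, 2, 2)
        assert np.array_equal(out[0, 0], [[1.0, 2.0], [3.0, 4.0]])

    @pytest.mark.parametrize("r", [1, 2, 3])
    def test_round_trip_exact(self, rng, r):
        x = rng.normal(size=(2, 2 * r * r, 6, 6))
        back = pixel_unshuffle(pixel_shuffle(x, r), r).numpy()
        assert np.array_equal(back, x)

    def test_multiset_preserved(self, rng):
        x = rng.normal(size=(1, 8, 6, 6))
        out = pixel_shuffle(x, 2).numpy()
        assert np.array_equal(np.sort(out.ravel()), np.sort(x.ravel()))

    def test_indivisible_channels_raise(self):
        with pytest.raises(ValueError):
            pixel_shuffle(np.ones((1, 3, 2, 2)), 2)


class TestConvBlock:
    def test_zero_input_zero_output(self):
        block = ConvBlock(4, 4, norm="instance")
        out = block(Tensor(np.zeros((1, 4, 8, 8))))
        assert np.allclose(out.numpy(), 0.0)

    def test_spectral_norm_bounded_by_svd_oracle(self, rng):
        block = ConvBlock(6, 8, use_spectral_norm=True, norm="none")
        block.conv.conv.weight.data = rng.normal(size=(8, 6, 3, 3)) * 3.0
        x = Tensor(rng.normal(size=(1, 6, 8, 8)))
        for _ in range(30):  # let power iteration converge
            block(x)
        w_eff = block.conv.effective_weight().numpy().reshape(8, -1)
        sigma_max = np.linalg.svd(w_eff, compute_uv=False)[0]
        assert sigma_max <= 1 + 1e-3

    def test_leaky_relu_slope(self):
        block = ConvBlock(1, 1, kernel_size=1, negative_slope=0.2,
                          use_spectral_norm=False, norm="none")
        block.conv.weight.data = np.ones((1, 1, 1, 1))
        block.conv.bias.data = np.zeros(1)
        out = block(Tensor(np.full((1, 1, 2, 2), -1.0)))
        assert np.allclose(out.numpy(), -0.2)

    def test_spatial_size_preserved(self, rng):
        block = ConvBlock(3, 5)
        out = block(Tensor(rng.normal(size=(1, 3, 11, 13))))
        assert out.shape == (1, 5, 11, 13)


class TestGates:
    def test_cse_zero_input(self):
        gate = CSEGate(4, reduction=2)
        out = gate(Tensor(np.zeros((1, 4, 4, 4))))
        assert np.allclose(out.numpy(), 0.0)

    def test_cse_zero_weights_halve(self, rng):
        gate = CSEGate(4, reduction=2)
        for p in gate.parameters():
            p.data = np.zeros_like(p.data)
        x = rng.normal(size=(1, 4, 5, 5))
        assert np.allclose(gate(Tensor(x)).numpy(), x / 2.0)

    def test_cse_contraction(self, rng):
        gate = CSEGate(8, reduction=2)
        x = rng.normal(size=(2, 8, 4, 4))
        out = gate(Tensor(x)).numpy()
        assert np.all(np.abs(out) <= np.abs(x) + 1e-12)

    def test_sse_zero_weights_halve(self, rng):
        gate = SSEGate(4)
        gate.conv.weight.data = np.zeros_like(gate.conv.weight.data)
        gate.conv.bias.data = np.zeros_like(gate.conv.bias.data)
        x = rng.normal(size=(1, 4, 5, 5))
        assert np.allclose(gate(Tensor(x)).numpy(), x / 2.0)

    def test_sse_gate_shared_across_channels(self, rng):
        gate = SSEGate(6)
        x = Tensor(rng.normal(size=(1, 6, 4, 4)))
        g = gate.gate(x).numpy()
        out = gate(x).numpy()
        ratio = out / x.numpy()
        assert np.allclose(ratio, np.broadcast_to(g, ratio.shape), atol=1e-10)

    def test_sse_saturation(self, rng):
        gate = SSEGate(3)
        gate.conv.weight.data = np.ones_like(gate.conv.weight.data)
        gate.conv.bias.data = np.full(1, 50.0)
        x = rng.uniform(0.1, 1.0, size=(1, 3, 4, 4))
        assert np.allclose(gate(Tensor(x)).numpy(), x, atol=1e-6)

    def test_gates_bounded(self, rng):
        cse, sse = CSEGate(4, 2), SSEGate(4)
        x = Tensor(rng.normal(size=(1, 4, 6, 6)) * 10)
        for g in (cse.gate(x).numpy(), sse.gate(x).numpy()):
            assert np.all(g > 0) and np.all(g < 1)


class TestSCSE:
    def _cfg(self, mode, combine="max"):
        return BlockConfig(width=4, scse_mode=mode, scse_reduction=2,
                           scse_combine=combine)

    def test_branch_selection(self, rng):
        x = Tensor(rng.normal(size=(1, 4, 5, 5)))
        block = SCSEBlock(4, self._cfg("cse"))
        assert np.allclose(block(x).numpy(), block.cse(x).numpy())
        block = SCSEBlock(4, self._cfg("sse"))
        assert np.allclose(block(x).numpy(), block.sse(x).numpy())

    def test_none_is_identity(self, rng):
        x = rng.normal(size=(1, 4, 5, 5))
        block = SCSEBlock(4, self._cfg("none"))
        assert np.array_equal(block(Tensor(x)).numpy(), x)

    def test_max_of_identical_branches(self, rng):
        block = SCSEBlock(4, self._cfg("scse", "max"))
        x = Tensor(rng.normal(size=(1, 4, 5, 5)))
        a = block.cse(x).numpy()
        b = block.sse(x).numpy()
        out = block(x).numpy()
        assert np.allclose(out, np.maximum(a, b), atol=1e-10)

    def test_max_dominates_multiply_on_nonnegative(self, rng):
        cfg_max = self._cfg("scse", "max")
        block = SCSEBlock(4, cfg_max)
        x = Tensor(rng.uniform(0.0, 1.0, size=(1, 4, 5, 5)))
        out_max = block(x).numpy()
        a = block.cse(x).numpy()
        b = block.sse(x).numpy()
        # gates in (0,1) so branch outputs are nonnegative here
        assert np.all(out_max >= a * b / np.maximum(x.numpy(), 1e-12) - 1e-9)
        block.combine = "multiply"
        out_mult = block(x).numpy()
        assert np.all(out_max + 1e-9 >= out_mult)

    def test_unknown_combine_rejected(self):
        with pytest.raises(ValueError):
            BlockConfig(width=4, scse_combine="median")


class TestResidualBlock:
    def test_zero_branch_weights_identity(self, rng):
        cfg = BlockConfig(width=4, scse_mode="none")
        block = ResidualBlock(cfg, use_spectral_norm=False)
        block.conv2.weight.data = np.zeros_like(block.conv2.weight.data)
        block.conv2.bias.data = np.zeros_like(block.conv2.bias.data)
        x = rng.normal(size=(1, 4, 6, 6))
        trunk, res = block(Tensor(x))
        assert np.allclose(trunk.numpy(), x)
        assert np.allclose(res.numpy(), 0.0)

    def test_trunk_minus_input_is_residual(self, rng):
        cfg = BlockConfig(width=4)
        block = ResidualBlock(cfg, use_spectral_norm=False)
        x = rng.normal(size=(1, 4, 6, 6))
        trunk, res = block(Tensor(x))
        assert np.allclose(trunk.numpy() - x, res.numpy(), atol=1e-12)
        assert trunk.shape == res.shape == (1, 4, 6, 6)


def _np_conv(x, w, b, pad):
    """Plain numpy/scipy conv oracle: NCHW x, OIkk w."""
    n, c, h, wd = x.shape
    o = w.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    out = np.zeros((n, o, h, wd))
    for ni in range(n):
        for oi in range(o):
            acc = np.zeros((h, wd))
            for ci in range(c):
                acc += correlate2d(xp[ni, ci], w[oi, ci], mode="valid")
            out[ni, oi] = acc + b[oi]
    return out


def _np_instance_norm(x, gamma, beta, eps=1e-5):
    mu = x.mean(axis=(2, 3), keepdims=True)
    var = x.var(axis=(2, 3), keepdims=True)
    y = (x - mu) / np.sqrt(var + eps)
    return y * gamma.reshape(1, -1, 1, 1) + beta.reshape(1, -1, 1, 1)


def _np_leaky(x, slope=0.2):
    return np.where(x > 0, x, slope * x)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class TestHFS:
    def test_zero_fuse_is_identity(self, rng):
        cfg = BlockConfig(width=4)
        mod = HFSModule(cfg, use_spectral_norm=False)
        mod.zero_init_fuse()
        x = rng.normal(size=(1, 4, 8, 8))
        assert np.allclose(mod(Tensor(x)).numpy(), x, atol=1e-12)

    def test_shape_preserved(self, rng):
        cfg = BlockConfig(width=8)
        mod = HFSModule(cfg, use_spectral_norm=False)
        out = mod(Tensor(rng.normal(size=(1, 8, 16, 16))))
        assert out.shape == (1, 8, 16, 16)

    def test_matches_straight_line_oracle(self, rng):
        """Recompose the whole module arithmetic in plain numpy/scipy."""
        cfg = BlockConfig(width=4, scse_mode="scse", scse_reduction=2,
                          scse_combine="max")
        mod = HFSModule(cfg, use_spectral_norm=False)
        for p in mod.parameters():  # small fixed random weights
            p.data = rng.normal(size=p.data.shape) * 0.1
        x = rng.normal(size=(1, 4, 8, 8))

        def np_scse(block, v):
            pooled = v.mean(axis=(2, 3))
            hidden = np.maximum(pooled @ block.scse.cse.w1.data
                                + block.scse.cse.b1.data, 0.0)
            cg = _sigmoid(hidden @ block.scse.cse.w2.data + block.scse.cse.b2.data)
            a = v * cg.reshape(v.shape[0], -1, 1, 1)
            sg = _sigmoid(_np_conv(v, block.scse.sse.conv.weight.data,
                                   block.scse.sse.conv.bias.data, pad=0))
            b = v * sg
            return np.maximum(a, b)

        trunk = x
        residuals = []
        for block in mod.blocks:
            cb = block.block1
            v = _np_conv(trunk, cb.conv.weight.data, cb.conv.bias.data, pad=1)
            v = _np_instance_norm(v, cb.norm.gamma.data, cb.norm.beta.data)
            v = _np_leaky(v, cb.act.negative_slope)
            v = _np_conv(v, block.conv2.weight.data, block.conv2.bias.data, pad=1)
            v = np_scse(block, v)
            residuals.append(v)
            trunk = trunk + v
        cat = np.concatenate(residuals + [trunk], axis=1)
        fused = _np_conv(cat, mod.fuse.weight.data, mod.fuse.bias.data, pad=0)
        expected = x + fused

        assert np.allclose(mod(Tensor(x)).numpy(), expected, atol=1e-6)
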